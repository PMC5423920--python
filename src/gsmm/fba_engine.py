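"""Linear-programming core: FBA, parsimonious FBA, ATP turnover, knockouts.

Flux balance analysis solves

    max/min  Z = c^T v
    s.t.     S v = 0,   lb <= v <= ub

with S the m x n stoichiometric matrix.  All solves go through scipy's
HiGHS interface with tight fixed tolerances and deterministic options so
repeated runs give identical answers.  Because FBA flux vectors are
non-unique at the optimum, only Z is treated as canonical; any flux-level
comparison downstream must use :func:`pfba`, which returns the
minimum-total-flux vector among the optimal ones.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .model_core import FluxSolution, MetabolicModel, evaluate_gpr

logger = logging.getLogger(__name__)

#: Feasibility/optimality tolerance requested from the solver.
SOLVER_TOLERANCE = 1e-9
#: Looser tolerance used when asserting S.v ~ 0 and bound satisfaction post hoc.
CHECK_TOLERANCE = 1e-7
#: Relative slack when pinning the FBA optimum inside the pFBA subproblem.
PFBA_OPTIMUM_SLACK = 1e-9

_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": SOLVER_TOLERANCE,
    "dual_feasibility_tolerance": SOLVER_TOLERANCE,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class SolverError(RuntimeError):
    """The LP could not be solved to optimality; carries the solver status."""

    def __init__(self, message: str, status: str):
        self.status = status
        super().__init__(message)


class InfeasibleError(SolverError):
    def __init__(self, message: str):
        super().__init__(message, status="infeasible")


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    result = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS.get(result.status, "numerical")
    if status in {"iteration_limit", "numerical"}:
        raise SolverError(f"LP solve failed: {result.message}", status=status)
    return result, status


def fba(model: MetabolicModel, objective_sense: str = "max") -> FluxSolution:
    """Flux balance analysis of ``model``; returns an audited solution.

    Raises :class:`SolverError` on numerical failure; infeasible and
    unbounded problems are reported via ``FluxSolution.status``, never as a
    silent zero.
    """
    if objective_sense not in {"max", "min"}:
        raise ValueError(f"objective_sense must be 'max' or 'min', got {objective_sense!r}")
    c = model.objective_vector()
    if not np.any(c):
        raise ValueError("model objective has no nonzero coefficient")
    S = model.stoichiometric_matrix()
    bounds = model.bounds()
    sign = -1.0 if objective_sense == "max" else 1.0
    result, status = _solve(sign * c, S, np.zeros(S.shape[0]), bounds)
    logger.debug("fba status=%s objective=%s", status, getattr(result, "fun", None))
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={}, tolerance_used=CHECK_TOLERANCE)
    v = result.x
    _audit(model, S, bounds, v)
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes={rid: float(v[j]) for j, rid in enumerate(model.reaction_ids)},
        tolerance_used=CHECK_TOLERANCE,
    )


def _audit(model: MetabolicModel, S, bounds, v) -> None:
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    if residual > CHECK_TOLERANCE:
        raise SolverError(f"steady-state residual {residual:.2e} exceeds tolerance", status="numerical")
    for j, (lb, ub) in enumerate(bounds):
        if v[j] < lb - CHECK_TOLERANCE or v[j] > ub + CHECK_TOLERANCE:
            raise SolverError(
                f"flux {model.reaction_ids[j]}={v[j]:.6g} violates bounds [{lb}, {ub}]",
                status="numerical",
            )


def pfba(model: MetabolicModel, objective_sense: str = "max") -> FluxSolution:
    """Parsimonious FBA: minimal total absolute flux at the FBA optimum.

    Each reaction is split into nonnegative forward/reverse halves and the
    sum of all halves is minimized subject to the steady state, the original
    box bounds, and the objective pinned to the FBA optimum with relative
    slack ``PFBA_OPTIMUM_SLACK`` (a one-sided bound, for numerical
    robustness).  The reported objective value equals the FBA optimum within
    that slack.
    """
    base = fba(model, objective_sense)
    if not base.optimal:
        raise InfeasibleError(f"FBA did not reach an optimum (status {base.status})") \
            if base.status == "infeasible" else SolverError(
            f"FBA did not reach an optimum (status {base.status})", status=base.status
        )
    z_star = base.objective_value
    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    c = model.objective_vector()
    # variables: forward halves f (n) then reverse halves r (n); v = f - r
    split_bounds = [(max(0.0, lb), max(0.0, ub)) for lb, ub in model.bounds()] + [
        (max(0.0, -ub), max(0.0, -lb)) for lb, ub in model.bounds()
    ]
    A_eq = np.hstack([S, -S])
    c_split = np.hstack([c, -c])
    slack = abs(z_star) * PFBA_OPTIMUM_SLACK + 1e-12
    if objective_sense == "max":
        A_ub = -c_split[None, :]
        b_ub = np.array([-(z_star - slack)])
    else:
        A_ub = c_split[None, :]
        b_ub = np.array([z_star + slack])
    result, status = _solve(
        np.ones(2 * n), A_eq, np.zeros(S.shape[0]), split_bounds, A_ub=A_ub, b_ub=b_ub
    )
    if status != "optimal":
        raise SolverError(f"pFBA subproblem ended with status {status}", status=status)
    v = result.x[:n] - result.x[n:]
    _audit(model, S, model.bounds(), v)
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes={rid: float(v[j]) for j, rid in enumerate(model.reaction_ids)},
        tolerance_used=CHECK_TOLERANCE,
    )


def total_flux(solution: FluxSolution) -> float:
    return float(sum(abs(v) for v in solution.fluxes.values()))


#: Reaction ids recognised as the ATP maintenance hydrolysis reaction.
MAINTENANCE_IDS = ("ATPM", "NGAM", "atp_maintenance", "ATPM_c")


def find_maintenance_reaction(model: MetabolicModel, maintenance_id: str | None = None) -> str:
    if maintenance_id is not None:
        if maintenance_id not in set(model.reaction_ids):
            raise KeyError(f"maintenance reaction {maintenance_id!r} not in model")
        return maintenance_id
    for candidate in MAINTENANCE_IDS:
        if candidate in set(model.reaction_ids):
            return candidate
    raise KeyError(
        "no ATP maintenance reaction found; pass maintenance_id explicitly "
        f"(looked for {MAINTENANCE_IDS})"
    )


def maximize_atp_turnover(
    model: MetabolicModel,
    fixed_rates: Mapping[str, float],
    maintenance_id: str | None = None,
    growth_rate: float | None = None,
    band: float = 0.0,
) -> float:
    """Maximum flux through the ATP maintenance reaction at measured rates.

    ``fixed_rates`` pins exchange reactions (and any other measured
    reaction) to observed values; ``growth_rate`` pins the biomass reaction.
    ``band`` optionally relaxes each pin to +/- band * |value| to absorb
    measurement error (default 0: exact equalities).  The returned flux is
    the condition's total maintenance ATP turnover r_ATP.

    On infeasibility, each pinned rate is relaxed in turn to identify a
    binding constraint, and the error message names it.
    """
    atpm = find_maintenance_reaction(model, maintenance_id)
    pins = dict(fixed_rates)
    if growth_rate is not None:
        if model.biomass_id is None:
            raise ValueError("growth_rate given but model has no biomass reaction")
        pins[model.biomass_id] = growth_rate

    def _pinned(skip: str | None) -> MetabolicModel:
        pinned = model.copy()
        for rxn_id, value in pins.items():
            if rxn_id == skip:
                continue
            rxn = pinned.reaction(rxn_id)
            half_width = abs(value) * band
            rxn.lower_bound = value - half_width
            rxn.upper_bound = value + half_width
        maint = pinned.reaction(atpm)
        maint.lower_bound, maint.upper_bound = 0.0, abs(maint.upper_bound) or 1000.0
        pinned.objective = {atpm: 1.0}
        return pinned

    solution = fba(_pinned(skip=None), "max")
    if solution.optimal:
        return solution.fluxes[atpm]
    if solution.status == "unbounded":
        raise SolverError("ATP turnover is unbounded under the fixed rates", status="unbounded")
    for rxn_id in pins:
        if fba(_pinned(skip=rxn_id), "max").optimal:
            raise InfeasibleError(
                f"fixed rates are infeasible; relaxing {rxn_id!r} "
                f"(= {pins[rxn_id]}) restores feasibility"
            )
    raise InfeasibleError("fixed rates are jointly infeasible (no single binding constraint)")


def apply_gene_deletion(model: MetabolicModel, genes: set[str] | frozenset[str]) -> MetabolicModel:
    """Copy of ``model`` with reactions disabled per the GPR Boolean rules.

    A reaction whose GPR evaluates False with the given genes deleted gets
    lb = ub = 0; GPR-less (spontaneous/orphan) reactions are never touched.
    """
    genes = set(genes)
    unknown = sorted(genes - model.genes)
    if unknown:
        raise KeyError(f"unknown gene ids: {', '.join(unknown)}")
    knocked = model.copy()
    for rxn in knocked.reactions:
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return knocked
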