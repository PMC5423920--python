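"""Phenotype prediction: single-gene essentiality and growth-source screens.

Essentiality follows the three-class convention: a gene is *essential* when
the knockout growth rate is numerically zero, *non-essential* when it equals
the wild-type maximum, and *partially essential* in between.  The printed
"zero" and "same as maximum" thresholds are made numerically explicit
(``eps_zero``, ``delta``) and configurable.

Growth-source screening opens one candidate carbon (or nitrogen) source at a
time while all other exchanges able to supply that element are closed; a
source is growth supporting when predicted growth exceeds the zero
threshold.  Elemental content is computed from the metabolites' parsed
formulas, so a candidate with an unparseable formula is flagged
``unscreenable`` rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .fba_engine import apply_gene_deletion, fba
from .model_core import MediumSpec, MetabolicModel, apply_medium
from .model_qc import FormulaError, is_generic_formula, parse_formula

#: Growth below this is "zero" (1/h); the class boundary for essential.
EPS_ZERO = 1e-6
#: Relative shortfall below which knockout growth counts as wild type.
DELTA = 1e-3


@dataclass
class GeneDeletionResult:
    gene: str
    mu_ko: float
    mu_wt: float
    essentiality: str  # essential | partially_essential | non_essential

    @property
    def growth_ratio(self) -> float:
        return self.mu_ko / self.mu_wt


def classify_growth(mu_ko: float, mu_wt: float, eps_zero: float = EPS_ZERO, delta: float = DELTA) -> str:
    if mu_ko < eps_zero:
        return "essential"
    if mu_ko >= (1.0 - delta) * mu_wt:
        return "non_essential"
    return "partially_essential"


def classify_essentiality(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    genes: Iterable[str] | None = None,
    eps_zero: float = EPS_ZERO,
    delta: float = DELTA,
) -> list[GeneDeletionResult]:
    """Single-gene deletion scan over ``genes`` (default: all model genes).

    For each gene the GPR-disabled model is re-solved by FBA and the
    knockout growth rate classified against the wild type.  Classification
    depends only on objective values, so it is stable to alternate optima.
    """
    base = apply_medium(model, medium) if medium is not None else model
    wild = fba(base, "max")
    if not wild.optimal or wild.objective_value < eps_zero:
        raise ValueError("wild type does not grow on this medium")
    mu_wt = wild.objective_value
    results = []
    for gene in sorted(genes if genes is not None else base.genes):
        solution = fba(apply_gene_deletion(base, {gene}), "max")
        mu_ko = solution.objective_value if solution.optimal else 0.0
        mu_ko = min(max(mu_ko, 0.0), mu_wt)
        results.append(
            GeneDeletionResult(
                gene=gene,
                mu_ko=mu_ko,
                mu_wt=mu_wt,
                essentiality=classify_growth(mu_ko, mu_wt, eps_zero, delta),
            )
        )
    return results


def essentiality_counts(results: Sequence[GeneDeletionResult]) -> dict[str, int]:
    counts = {"essential": 0, "partially_essential": 0, "non_essential": 0}
    for res in results:
        counts[res.essentiality] += 1
    return counts


# ---------------------------------------------------------------------------
# Growth-source screening
# ---------------------------------------------------------------------------


@dataclass
class SourceScreenResult:
    source: str  # exchange reaction id
    role: str  # carbon | nitrogen
    mu: float
    growth_supporting: bool
    screenable: bool = True
    note: str = ""


_ROLE_ELEMENT = {"carbon": "C", "nitrogen": "N"}


def _element_count(model: MetabolicModel, exchange_id: str, element: str) -> int | None:
    """Atoms of ``element`` in the exchanged metabolite; None if unknown."""
    rxn = model.reaction(exchange_id)
    met = model.metabolite(next(iter(rxn.stoichiometry)))
    if not met.formula:
        return None
    try:
        counts = parse_formula(met.formula)
    except FormulaError:
        return None
    if is_generic_formula(counts):
        return None
    return counts.get(element, 0)


def screen_growth_sources(
    model: MetabolicModel,
    base_medium: MediumSpec,
    candidates: Sequence[tuple[str, str]],
    uptake_rate: float = 10.0,
    per_carbon_normalize: bool = True,
    growth_threshold: float = EPS_ZERO,
) -> list[SourceScreenResult]:
    """FBA growth screen over candidate carbon/nitrogen sources.

    ``base_medium`` describes the background medium (minerals, oxygen, the
    fixed nitrogen source for carbon screens or the fixed glucose source for
    nitrogen screens).  For each candidate ``(exchange_id, role)`` the
    screen closes the uptake of every *other* exchange whose metabolite
    contains the role element, opens the candidate at ``-uptake_rate``
    (for carbon sources optionally normalized so the carbon supply equals a
    6-carbon reference, i.e. rate * 6 / n_C), and solves FBA.
    """
    exchange_ids = {r.id for r in model.exchange_reactions}
    results = []
    for exchange_id, role in candidates:
        if role not in _ROLE_ELEMENT:
            raise ValueError(f"role must be carbon or nitrogen, got {role!r}")
        if exchange_id not in exchange_ids:
            raise ValueError(f"candidate {exchange_id!r} is not an exchange reaction")
        element = _ROLE_ELEMENT[role]
        n_atoms = _element_count(model, exchange_id, element)
        if n_atoms is None:
            results.append(
                SourceScreenResult(
                    source=exchange_id,
                    role=role,
                    mu=float("nan"),
                    growth_supporting=False,
                    screenable=False,
                    note="unparseable or missing formula",
                )
            )
            continue
        if n_atoms == 0:
            results.append(
                SourceScreenResult(
                    source=exchange_id,
                    role=role,
                    mu=float("nan"),
                    growth_supporting=False,
                    screenable=False,
                    note=f"metabolite contains no {role}",
                )
            )
            continue
        bounds = dict(base_medium.items())
        for other in exchange_ids:
            if other == exchange_id:
                continue
            other_count = _element_count(model, other, element)
            if other_count is None or other_count > 0:
                lb, ub = bounds.get(other, (0.0, model.reaction(other).upper_bound))
                bounds[other] = (max(lb, 0.0), ub)
        rate = uptake_rate
        if role == "carbon" and per_carbon_normalize:
            rate = uptake_rate * 6.0 / n_atoms
        bounds[exchange_id] = (-rate, 0.0)
        solution = fba(apply_medium(model, MediumSpec(bounds)), "max")
        mu = solution.objective_value if solution.optimal else 0.0
        results.append(
            SourceScreenResult(
                source=exchange_id,
                role=role,
                mu=mu,
                growth_supporting=solution.optimal and mu > growth_threshold,
            )
        )
    return results
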