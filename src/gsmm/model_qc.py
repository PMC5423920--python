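"""Model quality control: mass/charge balance, gap detection, summaries.

Every reaction is checked for elemental and charge conservation from the
metabolites' formula and charge annotations (protonation states at pH 7.2).
Charge is treated as one extra pseudo-element so a single residual vector
covers both checks.  Dead-end metabolites are found by a direction-aware
scan of the stoichiometric matrix (the gapFind-style "root" definition),
with an optional transitive mode that propagates blockage through the
network until a fixed point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .model_core import MetabolicModel, Metabolite, Reaction

#: Pseudo-elements denoting generic residues; formulas containing them parse
#: but cannot support an exact balance verdict.
GENERIC_ELEMENTS = frozenset({"R", "X"})

#: Key under which the charge residual is stored alongside element residuals.
CHARGE_KEY = "charge"


class FormulaError(ValueError):
    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula into element -> count.

    Accepts sequences of one-or-two-letter element symbols each followed by
    an optional integer count (default 1); no parentheses.  The generic
    pseudo-elements R and X are accepted (callers must treat formulas
    containing them as undeterminable for balancing).
    """
    formula = formula.strip()
    if not formula:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        match = _ELEMENT.match(formula, pos)
        if match is None or match.start() != pos:
            raise FormulaError(
                f"illegal character {formula[pos]!r} in formula {formula!r}", position=pos
            )
        element = match.group(1)
        count = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return counts


def is_generic_formula(counts: dict[str, int]) -> bool:
    return bool(GENERIC_ELEMENTS & counts.keys())


@dataclass
class BalanceReport:
    """Per-reaction conservation residuals (products minus substrates)."""

    reaction_id: str
    element_residuals: dict[str, Fraction] = field(default_factory=dict)
    charge_residual: Fraction = Fraction(0)
    status: str = "undeterminable"  # balanced | imbalanced | undeterminable
    reason: str = ""

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_reaction_balance(
    reaction: Reaction, metabolite_table: dict[str, Metabolite]
) -> BalanceReport:
    """Check elemental and charge conservation of one reaction.

    Residual per element is sum(coefficient * count) over participants;
    status is ``balanced`` iff every residual (including charge) is exactly
    zero, ``undeterminable`` when any participant has an empty or
    unparseable formula or a generic R/X group, and exchange reactions are
    undeterminable by construction (they cross the system boundary).
    """
    report = BalanceReport(reaction_id=reaction.id)
    if reaction.is_exchange:
        report.reason = "exchange reaction (boundary by construction)"
        return report
    residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for met_id, coeff in reaction.stoichiometry.items():
        if met_id not in metabolite_table:
            raise KeyError(f"reaction {reaction.id}: metabolite {met_id!r} missing from table")
        met = metabolite_table[met_id]
        if not met.formula:
            report.reason = f"metabolite {met.id} has no formula"
            return report
        try:
            counts = parse_formula(met.formula)
        except FormulaError as exc:
            report.reason = f"metabolite {met.id}: {exc}"
            return report
        if is_generic_formula(counts):
            report.reason = f"metabolite {met.id} carries a generic R/X group"
            return report
        for element, count in counts.items():
            residuals[element] = residuals.get(element, Fraction(0)) + coeff * count
        charge += coeff * met.charge
    report.element_residuals = {e: r for e, r in residuals.items() if r != 0}
    report.charge_residual = charge
    report.status = "balanced" if not report.element_residuals and charge == 0 else "imbalanced"
    return report


def check_model_balance(model: MetabolicModel) -> list[BalanceReport]:
    table = {m.id: m for m in model.metabolites}
    return [check_reaction_balance(r, table) for r in model.reactions]


def balance_report_frame(reports: list[BalanceReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        residuals = dict(rep.element_residuals)
        if rep.charge_residual != 0:
            residuals[CHARGE_KEY] = rep.charge_residual
        rows.append(
            {
                "reaction": rep.reaction_id,
                "status": rep.status,
                "residuals": ";".join(f"{k}:{v}" for k, v in residuals.items()),
                "reason": rep.reason,
            }
        )
    return pd.DataFrame(rows, columns=["reaction", "status", "residuals", "reason"])


# ---------------------------------------------------------------------------
# Dead-end metabolites
# ---------------------------------------------------------------------------


@dataclass
class GapReport:
    no_production: set[str] = field(default_factory=set)
    no_consumption: set[str] = field(default_factory=set)

    @property
    def dead_end(self) -> set[str]:
        return self.no_production | self.no_consumption


def _scan_dead_ends(model: MetabolicModel, blocked: set[str]) -> GapReport:
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in blocked:
            continue
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if (coeff > 0 and forward) or (coeff < 0 and backward):
                producible.add(met_id)
            if (coeff < 0 and forward) or (coeff > 0 and backward):
                consumable.add(met_id)
    all_ids = set(model.metabolite_ids)
    return GapReport(
        no_production=all_ids - producible, no_consumption=all_ids - consumable
    )


def _directions(rxn) -> list[tuple[set[str], set[str]]]:
    """Admissible (substrates, products) pairs for a reaction's directions."""
    out = []
    substrates = {m for m, c in rxn.stoichiometry.items() if c < 0}
    products = {m for m, c in rxn.stoichiometry.items() if c > 0}
    if rxn.upper_bound > 0:
        out.append((substrates, products))
    if rxn.lower_bound < 0:
        out.append((products, substrates))
    return out


def _reachable_fixpoint(model: MetabolicModel, forward: bool) -> set[str]:
    """Metabolites reachable from boundary inflows (forward=True) or able to
    reach boundary outflows (forward=False), expanding one reaction direction
    at a time once all of its inputs (resp. outputs) are already covered."""
    covered: set[str] = set()
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions:
            for substrates, products in _directions(rxn):
                need, gain = (substrates, products) if forward else (products, substrates)
                if need <= covered and not gain <= covered:
                    covered |= gain
                    changed = True
    return covered


def find_dead_end_metabolites(model: MetabolicModel, transitive: bool = False) -> GapReport:
    """Find metabolites no reaction can produce and/or consume.

    Root mode (default): a metabolite cannot be produced when no reaction
    has it with (positive coefficient and ub > 0) or (negative coefficient
    and lb < 0); symmetrically for consumption.  Exchange reactions count as
    producers/consumers, so boundary metabolites with an open exchange are
    never dead ends.

    Transitive mode propagates blockage through the network: a metabolite is
    producible only when some reaction direction whose substrates are all
    themselves producible makes it, and consumable only when some reaction
    direction whose products are all themselves consumable removes it (an
    open exchange seeds both sets).  The two questions are propagated
    independently, mirroring the LP producibility/consumability oracle
    (which drains or supplies exactly one metabolite at a time); the match
    is exact except for fully internal stoichiometrically coupled cycles,
    which the reachability relaxation cannot see.
    """
    if not transitive:
        return _scan_dead_ends(model, blocked=set())
    all_ids = set(model.metabolite_ids)
    return GapReport(
        no_production=all_ids - _reachable_fixpoint(model, forward=True),
        no_consumption=all_ids - _reachable_fixpoint(model, forward=False),
    )


# ---------------------------------------------------------------------------
# Model summary
# ---------------------------------------------------------------------------

TRANSPORT_CLASS = "intercompartmental/transport"


def strip_compartment(met: Metabolite) -> str:
    """Base identity of a metabolite with the compartment tag removed."""
    for suffix in (f"_{met.compartment}", f"[{met.compartment}]"):
        if met.id.endswith(suffix):
            return met.id[: -len(suffix)]
    return met.id


def summarize_model(model: MetabolicModel) -> dict[str, int | dict[str, int]]:
    """Headline counts: genes, reactions, metabolites, reactions by location.

    Metabolites are counted both as total entries (one per compartmented
    species) and as compartment-stripped unique species.  A reaction whose
    metabolites span more than one compartment is classed as
    intercompartmental/transport; the per-class counts sum to the reaction
    total.
    """
    by_compartment: dict[str, int] = {}
    for rxn in model.reactions:
        comps = {model.metabolite(m).compartment for m in rxn.stoichiometry}
        key = TRANSPORT_CLASS if len(comps) > 1 else next(iter(comps), "empty")
        by_compartment[key] = by_compartment.get(key, 0) + 1
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "metabolites_total": len(model.metabolites),
        "metabolites_unique": len({strip_compartment(m) for m in model.metabolites}),
        "reactions_by_compartment": by_compartment,
    }
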