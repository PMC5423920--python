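"""Domain types for genome-scale metabolic models and their serialization.

A model is a set of compartmented metabolites, stoichiometrically defined
reactions with flux bounds and Boolean gene-protein-reaction (GPR) rules, and
a linear objective (usually growth).  Stoichiometric coefficients are stored
as exact rationals so that round-trips through the tabular dialect never
drift; flux bounds are floats with the conventional ±1000 sentinels for
"unconstrained".  Exchange reactions are single-metabolite boundary reactions
with the sign convention uptake < 0 < secretion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class ValidationError(ValueError):
    """A model (or model file) violates a structural invariant.

    ``messages`` lists every offending item, not just the first.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class GPRParseError(ValueError):
    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


class GPRExpression:
    """Boolean AND/OR tree over gene identifiers.

    Evaluation semantics: a gene is ``True`` when present (not deleted /
    expressed, depending on context).  AND models an enzyme complex, OR a set
    of isozymes.
    """

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, false_genes: Iterable[str] = ()) -> bool:
        """Evaluate with the given genes set to False and all others True."""
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class GPRLeaf(GPRExpression):
    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def evaluate(self, false_genes: Iterable[str] = ()) -> bool:
        return self.gene not in set(false_genes)

    def to_string(self) -> str:
        return self.gene


def _flatten(cls, children: Sequence[GPRExpression]) -> tuple[GPRExpression, ...]:
    out: list[GPRExpression] = []
    for child in children:
        if isinstance(child, cls):
            out.extend(child.children)
        else:
            out.append(child)
    seen: set[str] = set()
    unique: list[GPRExpression] = []
    for child in out:
        key = child.to_string()
        if key not in seen:
            seen.add(key)
            unique.append(child)
    return tuple(unique)


@dataclass(frozen=True, init=False)
class GPRAnd(GPRExpression):
    children: tuple[GPRExpression, ...]

    def __init__(self, children: Sequence[GPRExpression]):
        object.__setattr__(self, "children", _flatten(GPRAnd, children))
        if len(self.children) < 2:
            raise GPRParseError("AND node requires at least 2 distinct children")

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, false_genes: Iterable[str] = ()) -> bool:
        false_set = set(false_genes)
        return all(c.evaluate(false_set) for c in self.children)

    def to_string(self) -> str:
        parts = [
            f"({c.to_string()})" if isinstance(c, GPROr) else c.to_string()
            for c in self.children
        ]
        return " and ".join(parts)


@dataclass(frozen=True, init=False)
class GPROr(GPRExpression):
    children: tuple[GPRExpression, ...]

    def __init__(self, children: Sequence[GPRExpression]):
        object.__setattr__(self, "children", _flatten(GPROr, children))
        if len(self.children) < 2:
            raise GPRParseError("OR node requires at least 2 distinct children")

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, false_genes: Iterable[str] = ()) -> bool:
        false_set = set(false_genes)
        return any(c.evaluate(false_set) for c in self.children)

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


def gpr_and(children: Sequence[GPRExpression]) -> GPRExpression:
    """AND combinator that collapses a single distinct child to itself."""
    flat = _flatten(GPRAnd, children)
    if len(flat) == 0:
        raise GPRParseError("empty AND")
    if len(flat) == 1:
        return flat[0]
    return GPRAnd(flat)


def gpr_or(children: Sequence[GPRExpression]) -> GPRExpression:
    flat = _flatten(GPROr, children)
    if len(flat) == 0:
        raise GPRParseError("empty OR")
    if len(flat) == 1:
        return flat[0]
    return GPROr(flat)


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize_gpr(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        match = _GPR_TOKEN.match(text, pos)
        if match is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GPRParseError(
                f"illegal character {stripped[0]!r} in GPR rule", position=pos
            )
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


def parse_gpr(rule_text: str, known_genes: Iterable[str] | None = None) -> GPRExpression:
    """Parse a GPR rule string into a normalized Boolean tree.

    Grammar: gene tokens, ``and`` / ``or`` keywords (case-insensitive) and
    parentheses; ``and`` binds tighter than ``or``.  Nested nodes of the same
    operator are flattened and duplicate children dropped.  If ``known_genes``
    is given, any leaf outside that set raises :class:`GPRParseError`.
    """
    tokens = _tokenize_gpr(rule_text)
    if not tokens:
        raise GPRParseError("empty GPR rule", position=0)
    index = 0

    def peek() -> tuple[str, int] | None:
        return tokens[index] if index < len(tokens) else None

    def parse_or() -> GPRExpression:
        nonlocal index
        terms = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            index += 1
            terms.append(parse_and())
        return gpr_or(terms)

    def parse_and() -> GPRExpression:
        nonlocal index
        factors = [parse_atom()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            index += 1
            factors.append(parse_atom())
        return gpr_and(factors)

    def parse_atom() -> GPRExpression:
        nonlocal index
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", position=len(rule_text))
        word, pos = tok
        if word == "(":
            index += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parentheses", position=pos)
            index += 1
            return inner
        if word == ")":
            raise GPRParseError("unbalanced parentheses", position=pos)
        if word.lower() in {"and", "or"}:
            raise GPRParseError(f"misplaced keyword {word!r}", position=pos)
        index += 1
        return GPRLeaf(word)

    expr = parse_or()
    if index != len(tokens):
        raise GPRParseError(
            f"trailing tokens starting with {tokens[index][0]!r}",
            position=tokens[index][1],
        )
    if known_genes is not None:
        unknown = sorted(expr.genes() - set(known_genes))
        if unknown:
            raise GPRParseError(f"unknown gene tokens: {', '.join(unknown)}")
    return expr


def evaluate_gpr(expr: GPRExpression, deleted_genes: Iterable[str] = ()) -> bool:
    """True iff the rule is satisfied with ``deleted_genes`` absent."""
    return expr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    name: str = ""
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GPRExpression | None = None
    subsystem: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = {
            met: Fraction(coeff)
            for met, coeff in self.stoichiometry.items()
            if Fraction(coeff) != 0
        }

    @property
    def is_exchange(self) -> bool:
        """Single-metabolite boundary reaction (system in/outflow)."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        new = replace(self)
        new.stoichiometry = dict(self.stoichiometry)
        return new


@dataclass
class MediumSpec:
    """Bounds for exchange reactions: uptake = negative lower bound."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def items(self):
        return self.bounds.items()


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]
    tolerance_used: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A compartmented stoichiometric model with GPRs and a linear objective.

    Assembles the m x n stoichiometric matrix S (m metabolites, n reactions)
    on demand; the objective is the coefficient vector c over reactions, by
    default 1 on the biomass reaction.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        genes: Iterable[str] = (),
        compartments: Iterable[str] = (),
        objective: Mapping[str, float] | None = None,
        biomass_id: str | None = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.genes = set(genes)
        self.compartments = set(compartments) | {m.compartment for m in self.metabolites}
        self.biomass_id = biomass_id
        if objective is None and biomass_id is not None:
            objective = {biomass_id: 1.0}
        self.objective = dict(objective or {})
        self.validate()

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        errors: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        dup_mets = {i for i in met_ids if met_ids.count(i) > 1}
        if dup_mets:
            errors.append(f"duplicate metabolite ids: {sorted(dup_mets)}")
        rxn_ids = [r.id for r in self.reactions]
        dup_rxns = {i for i in rxn_ids if rxn_ids.count(i) > 1}
        if dup_rxns:
            errors.append(f"duplicate reaction ids: {sorted(dup_rxns)}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for met in self.metabolites:
            if met.compartment not in self.compartments:
                errors.append(
                    f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    errors.append(
                        f"reaction {rxn.id}: references undeclared metabolite {met_id!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                errors.append(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            if rxn.gpr is not None:
                missing = sorted(rxn.gpr.genes() - self.genes)
                if missing:
                    errors.append(
                        f"reaction {rxn.id}: GPR references unknown genes {missing}"
                    )
        for rxn_id in self.objective:
            if rxn_id not in self._rxn_index:
                errors.append(f"objective references unknown reaction {rxn_id!r}")
        if self.objective and not any(c != 0 for c in self.objective.values()):
            errors.append("objective has no nonzero coefficient")
        if self.biomass_id is not None and self.biomass_id not in self._rxn_index:
            errors.append(f"biomass reaction {self.biomass_id!r} not in model")
        if errors:
            raise ValidationError(errors)

    # -- matrix views -------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (m, n): metabolites x reactions."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = float(coeff)
        return S

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        rxn_pos = {r.id: j for j, r in enumerate(self.reactions)}
        for rxn_id, coeff in self.objective.items():
            c[rxn_pos[rxn_id]] = coeff
        return c

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m, annotations=dict(m.annotations)) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            compartments=set(self.compartments),
            objective=dict(self.objective),
            biomass_id=self.biomass_id,
            id=self.id,
        )


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: MediumSpec | Mapping[str, tuple[float, float]]) -> MetabolicModel:
    """Return a copy of ``model`` constrained to the given medium.

    Every exchange reaction not listed in the medium has its lower bound
    raised to 0 (no uptake); listed exchanges get exactly the given bounds.
    Internal reactions are untouched and the input model is never modified.
    """
    items = dict(medium.items() if hasattr(medium, "items") else medium)
    new = model.copy()
    exchange_ids = {r.id for r in new.exchange_reactions}
    bad = sorted(set(items) - exchange_ids)
    if bad:
        raise ValidationError(
            [f"medium key {rid!r} is not an exchange reaction" for rid in bad]
        )
    for rxn in new.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in items:
            lb, ub = items[rxn.id]
            rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return new


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

#: Columns of the tabular model dialect (TSV or CSV, UTF-8).
REACTION_COLUMNS = ["id", "name", "stoichiometry", "lower_bound", "upper_bound", "gpr", "subsystem", "objective_coefficient"]
METABOLITE_COLUMNS = ["id", "name", "compartment", "formula", "charge", "annotations"]


def format_coefficient(value: Fraction) -> str:
    """Serialize a rational exactly: decimal when terminating, else p/q."""
    value = Fraction(value)
    den = value.denominator
    twos = fives = 0
    while den % 2 == 0:
        den //= 2
        twos += 1
    while den % 5 == 0:
        den //= 5
        fives += 1
    if den != 1:
        return f"{value.numerator}/{value.denominator}"
    shift = max(twos, fives)
    scaled = value.numerator * 10**shift // value.denominator
    if shift == 0:
        return str(scaled)
    text = f"{scaled:+0{shift + 2}d}"  # sign + at least one integer digit
    sign = "-" if scaled < 0 else ""
    digits = text.lstrip("+-")
    return f"{sign}{digits[:-shift]}.{digits[-shift:]}".replace("-.", "-0.")


def parse_coefficient(text: str) -> Fraction:
    text = str(text).strip()
    if "/" in text:
        num, den = text.split("/")
        return Fraction(int(num), int(den))
    return Fraction(text)


def _format_stoichiometry(stoich: Mapping[str, Fraction]) -> str:
    return ";".join(f"{met}:{format_coefficient(coeff)}" for met, coeff in stoich.items())


def _parse_stoichiometry(text: str, rxn_id: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ValidationError(
                [f"reaction {rxn_id}: malformed stoichiometry term {part!r}"]
            )
        met, _, coeff = part.rpartition(":")
        out[met.strip()] = parse_coefficient(coeff)
    if not out:
        raise ValidationError([f"reaction {rxn_id}: empty stoichiometry"])
    return out


def _read_table(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def read_model_tables(
    reactions_path: str | Path,
    metabolites_path: str | Path,
    genes_path: str | Path | None = None,
    biomass_id: str | None = None,
    model_id: str = "model",
) -> MetabolicModel:
    """Load a model from the tabular dialect (TSV/CSV with headers).

    The genes file is a one-column table of gene ids; when omitted, the gene
    set is collected from the GPR rules.  The biomass reaction defaults to
    the one carrying a nonzero ``objective_coefficient``.
    """
    met_frame = _read_table(metabolites_path)
    for col in ("id", "compartment"):
        if col not in met_frame.columns:
            raise ValidationError([f"metabolites table missing column {col!r}"])
    metabolites = []
    for row in met_frame.to_dict("records"):
        annotations = {}
        for pair in str(row.get("annotations", "")).split(";"):
            if "=" in pair:
                key, _, val = pair.partition("=")
                annotations[key.strip()] = val.strip()
        metabolites.append(
            Metabolite(
                id=row["id"].strip(),
                name=str(row.get("name", "")),
                compartment=row["compartment"].strip(),
                formula=str(row.get("formula", "")).strip(),
                charge=int(row["charge"]) if str(row.get("charge", "")).strip() else 0,
                annotations=annotations,
            )
        )

    genes: set[str] = set()
    if genes_path is not None:
        gene_frame = _read_table(genes_path)
        if "id" not in gene_frame.columns:
            raise ValidationError(["genes table missing column 'id'"])
        genes = {g.strip() for g in gene_frame["id"] if g.strip()}

    rxn_frame = _read_table(reactions_path)
    for col in ("id", "stoichiometry"):
        if col not in rxn_frame.columns:
            raise ValidationError([f"reactions table missing column {col!r}"])
    reactions = []
    objective: dict[str, float] = {}
    for row in rxn_frame.to_dict("records"):
        rxn_id = row["id"].strip()
        gpr_text = str(row.get("gpr", "")).strip()
        gpr = parse_gpr(gpr_text) if gpr_text else None
        if gpr is not None and genes_path is None:
            genes |= gpr.genes()
        lb = float(row["lower_bound"]) if str(row.get("lower_bound", "")).strip() else DEFAULT_LOWER_BOUND
        ub = float(row["upper_bound"]) if str(row.get("upper_bound", "")).strip() else DEFAULT_UPPER_BOUND
        reactions.append(
            Reaction(
                id=rxn_id,
                name=str(row.get("name", "")),
                stoichiometry=_parse_stoichiometry(row["stoichiometry"], rxn_id),
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=str(row.get("subsystem", "")),
            )
        )
        coeff_text = str(row.get("objective_coefficient", "")).strip()
        if coeff_text and float(coeff_text) != 0:
            objective[rxn_id] = float(coeff_text)

    if biomass_id is None and len(objective) == 1:
        biomass_id = next(iter(objective))
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective=objective or None,
        biomass_id=biomass_id,
        id=model_id,
    )


def write_model_tables(model: MetabolicModel, directory: str | Path, prefix: str = "model") -> dict[str, Path]:
    """Write the tabular dialect; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula,
            "charge": m.charge,
            "annotations": ";".join(f"{k}={v}" for k, v in m.annotations.items()),
        }
        for m in model.metabolites
    ]
    rxn_rows = [
        {
            "id": r.id,
            "name": r.name,
            "stoichiometry": _format_stoichiometry(r.stoichiometry),
            "lower_bound": repr(r.lower_bound),
            "upper_bound": repr(r.upper_bound),
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
            "subsystem": r.subsystem,
            "objective_coefficient": model.objective.get(r.id, ""),
        }
        for r in model.reactions
    ]
    gene_rows = [{"id": g} for g in sorted(model.genes)]
    paths = {
        "reactions": directory / f"{prefix}_reactions.tsv",
        "metabolites": directory / f"{prefix}_metabolites.tsv",
        "genes": directory / f"{prefix}_genes.tsv",
    }
    pd.DataFrame(rxn_rows, columns=REACTION_COLUMNS).to_csv(paths["reactions"], sep="\t", index=False)
    pd.DataFrame(met_rows, columns=METABOLITE_COLUMNS).to_csv(paths["metabolites"], sep="\t", index=False)
    pd.DataFrame(gene_rows, columns=["id"]).to_csv(paths["genes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# SBML subset (Level 3 core + FBC v2)
# ---------------------------------------------------------------------------


class SBMLReadError(ValueError):
    pass


def _sbml_sanitize(identifier: str) -> str:
    # SBML SIds must match [A-Za-z_][A-Za-z0-9_]*
    sanitized = re.sub(r"[^A-Za-z0-9_]", "__", identifier)
    if not re.match(r"[A-Za-z_]", sanitized):
        sanitized = "x_" + sanitized
    return sanitized


def write_sbml_subset(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 with the FBC v2 extension.

    Species carry compartment, charge and chemical formula; reactions carry
    flux-bound parameters and gene-product associations; the active FBC
    objective holds the objective coefficients.  Metabolite annotation maps
    and subsystems are stored in notes so the round trip is lossless.
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_sanitize(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments):
        compartment = sbml_model.createCompartment()
        compartment.setId(_sbml_sanitize(comp))
        compartment.setName(comp)
        compartment.setConstant(True)

    def _set_notes(entity, pairs: Mapping[str, str]) -> None:
        if not pairs:
            return
        body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
        entity.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
        )

    met_sid = {}
    for met in model.metabolites:
        species = sbml_model.createSpecies()
        sid = "M_" + _sbml_sanitize(met.id)
        met_sid[met.id] = sid
        species.setId(sid)
        species.setName(met.name)
        species.setCompartment(_sbml_sanitize(met.compartment))
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)
        splug = species.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(met.formula)
        _set_notes(species, {"original_id": met.id, **met.annotations})

    gene_sid = {}
    for gene in sorted(model.genes):
        product = mplug.createGeneProduct()
        sid = "G_" + _sbml_sanitize(gene)
        gene_sid[gene] = sid
        product.setId(sid)
        product.setLabel(gene)

    def _bound_parameter(value: float, index: int, which: str) -> str:
        pid = f"fb_{index}_{which}"
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        return pid

    def _set_association(node, expr: GPRExpression) -> None:
        if isinstance(expr, GPRLeaf):
            ref = node.createGeneProductRef()
            ref.setGeneProduct(gene_sid[expr.gene])
        elif isinstance(expr, GPRAnd):
            inner = node.createAnd()
            for child in expr.children:
                _set_association(inner, child)
        elif isinstance(expr, GPROr):
            inner = node.createOr()
            for child in expr.children:
                _set_association(inner, child)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")

    for index, rxn in enumerate(model.reactions):
        reaction = sbml_model.createReaction()
        rid = "R_" + _sbml_sanitize(rxn.id)
        reaction.setId(rid)
        reaction.setName(rxn.name)
        reaction.setFast(False)
        reaction.setReversible(rxn.lower_bound < 0)
        rplug = reaction.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_parameter(rxn.lower_bound, index, "lb"))
        rplug.setUpperFluxBound(_bound_parameter(rxn.upper_bound, index, "ub"))
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = reaction.createReactant()
                ref.setStoichiometry(float(-coeff))
            else:
                ref = reaction.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(met_sid[met_id])
            ref.setConstant(True)
        if rxn.gpr is not None:
            assoc = rplug.createGeneProductAssociation()
            _set_association(assoc, rxn.gpr)
        notes = {"original_id": rxn.id}
        if rxn.subsystem:
            notes["subsystem"] = rxn.subsystem
        _set_notes(reaction, notes)
        coeff = model.objective.get(rxn.id, 0.0)
        if coeff:
            flux_obj = objective.createFluxObjective()
            flux_obj.setReaction(rid)
            flux_obj.setCoefficient(float(coeff))

    libsbml.writeSBMLToFile(doc, str(path))


def _parse_notes(entity) -> dict[str, str]:
    if not entity.isSetNotes():
        return {}
    text = entity.getNotesString()
    return {
        key.strip(): value.strip()
        for key, value in re.findall(r"<p>([^<:]+):\s*([^<]*)</p>", text)
    }


def read_sbml_subset(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 (+FBC) document into a :class:`MetabolicModel`.

    Malformed XML and structurally invalid documents raise
    :class:`SBMLReadError` listing the libsbml error log; unsupported
    constructs (e.g. species without a compartment) are reported, never
    silently dropped.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    errors = [
        doc.getError(i).getMessage().strip()
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        raise SBMLReadError("; ".join(errors))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError("document contains no model")
    mplug = sbml_model.getPlugin("fbc")

    def _original_id(entity, prefix: str) -> str:
        notes = _parse_notes(entity)
        if "original_id" in notes:
            return notes["original_id"]
        sid = entity.getId()
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    metabolites = []
    sid_to_id = {}
    for i in range(sbml_model.getNumSpecies()):
        species = sbml_model.getSpecies(i)
        if not species.isSetCompartment() or not species.getCompartment():
            raise SBMLReadError(f"species {species.getId()!r} has no compartment")
        notes = _parse_notes(species)
        met_id = notes.pop("original_id", None) or (
            species.getId()[2:] if species.getId().startswith("M_") else species.getId()
        )
        sid_to_id[species.getId()] = met_id
        splug = species.getPlugin("fbc")
        compartment_obj = sbml_model.getCompartment(species.getCompartment())
        compartment = (
            compartment_obj.getName() or compartment_obj.getId()
            if compartment_obj is not None
            else species.getCompartment()
        )
        metabolites.append(
            Metabolite(
                id=met_id,
                name=species.getName(),
                compartment=compartment,
                formula=splug.getChemicalFormula() if splug is not None and splug.isSetChemicalFormula() else "",
                charge=splug.getCharge() if splug is not None and splug.isSetCharge() else 0,
                annotations=notes,
            )
        )

    gene_label = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            product = mplug.getGeneProduct(i)
            gene_label[product.getId()] = product.getLabel() or product.getId()

    def _association_to_gpr(node) -> GPRExpression:
        import libsbml as _ls

        if isinstance(node, _ls.GeneProductRef):
            return GPRLeaf(gene_label.get(node.getGeneProduct(), node.getGeneProduct()))
        if isinstance(node, _ls.FbcAnd):
            return gpr_and([_association_to_gpr(node.getAssociation(i)) for i in range(node.getNumAssociations())])
        if isinstance(node, _ls.FbcOr):
            return gpr_or([_association_to_gpr(node.getAssociation(i)) for i in range(node.getNumAssociations())])
        raise SBMLReadError(f"unsupported gene association node {type(node).__name__}")

    reactions = []
    objective: dict[str, float] = {}
    rid_to_id = {}
    for i in range(sbml_model.getNumReactions()):
        reaction = sbml_model.getReaction(i)
        notes = _parse_notes(reaction)
        rxn_id = notes.get("original_id") or (
            reaction.getId()[2:] if reaction.getId().startswith("R_") else reaction.getId()
        )
        rid_to_id[reaction.getId()] = rxn_id
        stoich: dict[str, Fraction] = {}
        for k in range(reaction.getNumReactants()):
            ref = reaction.getReactant(k)
            met = sid_to_id[ref.getSpecies()]
            stoich[met] = stoich.get(met, Fraction(0)) - Fraction(ref.getStoichiometry())
        for k in range(reaction.getNumProducts()):
            ref = reaction.getProduct(k)
            met = sid_to_id[ref.getSpecies()]
            stoich[met] = stoich.get(met, Fraction(0)) + Fraction(ref.getStoichiometry())
        rplug = reaction.getPlugin("fbc")
        lb, ub = DEFAULT_LOWER_BOUND, DEFAULT_UPPER_BOUND
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = sbml_model.getParameter(rplug.getLowerFluxBound()).getValue()
        if rplug is not None and rplug.isSetUpperFluxBound():
            ub = sbml_model.getParameter(rplug.getUpperFluxBound()).getValue()
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(rplug.getGeneProductAssociation().getAssociation())
        reactions.append(
            Reaction(
                id=rxn_id,
                name=reaction.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=notes.get("subsystem", ""),
            )
        )

    if mplug is not None and mplug.getActiveObjective() is not None:
        active = mplug.getActiveObjective()
        for i in range(active.getNumFluxObjectives()):
            flux_obj = active.getFluxObjective(i)
            objective[rid_to_id[flux_obj.getReaction()]] = flux_obj.getCoefficient()

    biomass_id = next(iter(objective)) if len(objective) == 1 else None
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=set(gene_label.values()),
        objective=objective or None,
        biomass_id=biomass_id,
        id=sbml_model.getId() or "model",
    )
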