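"""Physiology-level analyses built on the LP core.

Covers four evaluation surfaces of a genome-scale model:

* **Maintenance energetics** — chemostat observations pin measured exchange
  rates and the growth rate; the maximal flux through the ATP maintenance
  hydrolysis gives the condition's total maintenance ATP turnover r_ATP, and
  ordinary least squares of r_ATP on the growth rate mu yields the
  growth-associated (GAM, slope, mmol ATP/gDCW) and non-growth-associated
  (NGAM, intercept, mmol ATP/gDCW/h) maintenance: r_ATP = GAM * mu + NGAM.
* **Chemostat phenotype** — FBA growth maximization at fixed glucose uptake
  rates, reading mu, qO2, qCO2 and the respiratory quotient RQ = qCO2/qO2
  from the parsimonious flux vector.
* **Biomass/NGAM sensitivity** — one macromolecule fraction (or NGAM) is
  varied at a time, the biomass equation rebuilt with the remaining
  fractions renormalized, and the growth response scanned over a glucose
  uptake grid.
* **Consistency scoring** — Pearson correlation between two flux vectors
  (e.g. pFBA vs 13C-derived), and coverage of the model's genes/reactions
  by a transcriptome expression call set via the GPR Boolean rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fba_engine import fba, maximize_atp_turnover, pfba
from .model_core import MetabolicModel, evaluate_gpr


# ---------------------------------------------------------------------------
# Chemostat observations and maintenance fitting
# ---------------------------------------------------------------------------


@dataclass
class ChemostatObservation:
    """One steady-state chemostat condition (mu = dilution rate D)."""

    dilution_rate: float  # 1/h
    rates: dict[str, float]  # exchange id -> measured rate, uptake negative

    def __post_init__(self) -> None:
        if not self.dilution_rate > 0:
            raise ValueError("dilution rate must be positive")
        if any(not np.isfinite(v) for v in self.rates.values()):
            raise ValueError("all measured rates must be finite")


@dataclass
class MaintenanceFit:
    gam: float  # Y_xATP, mmol ATP/gDCW
    ngam: float  # m_ATP, mmol ATP/gDCW/h
    mu: np.ndarray
    r_atp: np.ndarray
    residuals: np.ndarray
    n_points: int

    def predict(self, mu: float) -> float:
        return self.gam * mu + self.ngam


def fit_maintenance(
    observations: Sequence[ChemostatObservation],
    model: MetabolicModel,
    maintenance_id: str | None = None,
    band: float = 0.0,
) -> MaintenanceFit:
    """Fit GAM and NGAM from chemostat data via the model's ATP balance.

    For each observation the measured exchange rates and the growth rate are
    pinned (exact equalities by default; ``band`` relaxes each pin to
    +/- band * |value|) and the ATP maintenance flux maximized, giving
    r_ATP.  The line r_ATP = GAM * mu + NGAM is then fit by least squares.
    A negative fitted NGAM is returned as-is with a warning.
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 chemostat observations")
    mu = np.array([obs.dilution_rate for obs in observations], dtype=float)
    if np.ptp(mu) == 0:
        raise ValueError("all dilution rates are equal; the regression is singular")
    r_atp = np.array(
        [
            maximize_atp_turnover(
                model,
                obs.rates,
                maintenance_id=maintenance_id,
                growth_rate=obs.dilution_rate,
                band=band,
            )
            for obs in observations
        ]
    )
    design = np.column_stack([mu, np.ones_like(mu)])
    (slope, intercept), *_ = np.linalg.lstsq(design, r_atp, rcond=None)
    if intercept < 0:
        warnings.warn(
            f"fitted NGAM is negative ({intercept:.4g} mmol ATP/gDCW/h)", stacklevel=2
        )
    return MaintenanceFit(
        gam=float(slope),
        ngam=float(intercept),
        mu=mu,
        r_atp=r_atp,
        residuals=r_atp - design @ np.array([slope, intercept]),
        n_points=len(observations),
    )


# ---------------------------------------------------------------------------
# Biomass composition and its installation into a model
# ---------------------------------------------------------------------------

MACROMOLECULES = ("protein", "lipid", "rna", "dna", "carbohydrate", "small_molecule_pool")


@dataclass
class BiomassComposition:
    """Macromolecular mass fractions (g/gDCW) plus maintenance parameters."""

    protein: float = 0.42
    lipid: float = 0.112
    rna: float = 0.116
    dna: float = 0.0055
    carbohydrate: float = 0.319
    small_molecule_pool: float = 0.0275
    gam: float = 20.4  # mmol ATP/gDCW
    ngam: float = 2.52  # mmol ATP/gDCW/h

    def fractions(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MACROMOLECULES}

    def __post_init__(self) -> None:
        for name, value in self.fractions().items():
            if value < 0:
                raise ValueError(f"{name} fraction must be nonnegative")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be nonnegative")
        total = sum(self.fractions().values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1 g/gDCW (got {total:.6g})")

    def with_fraction(self, name: str, value: float, renormalize: str = "proportional") -> "BiomassComposition":
        """New composition with one fraction changed and the rest rescaled.

        ``proportional`` rescales all other fractions by a common factor so
        the total stays 1; ``carbohydrate`` absorbs the whole change into
        the carbohydrate fraction.
        """
        if name not in MACROMOLECULES:
            raise KeyError(f"unknown macromolecule {name!r}")
        if not 0 <= value < 1:
            raise ValueError(f"fraction {name}={value} cannot renormalize")
        updates = {name: value}
        if renormalize == "proportional":
            others = {k: v for k, v in self.fractions().items() if k != name}
            scale = (1.0 - value) / sum(others.values())
            updates.update({k: v * scale for k, v in others.items()})
        elif renormalize == "carbohydrate":
            if name == "carbohydrate":
                raise ValueError("cannot absorb a carbohydrate change into carbohydrate")
            new_carb = self.carbohydrate + (getattr(self, name) - value)
            if new_carb < 0:
                raise ValueError("carbohydrate fraction would become negative")
            updates["carbohydrate"] = new_carb
        else:
            raise ValueError(f"unknown renormalization mode {renormalize!r}")
        return replace(self, **updates)


@dataclass
class BiomassMapping:
    """Model ids of the biomass precursors and energy currency species."""

    precursors: dict[str, str] = field(
        default_factory=lambda: {
            "protein": "protein_c",
            "lipid": "lipid_c",
            "rna": "rna_c",
            "dna": "dna_c",
            "carbohydrate": "carbohydrate_c",
            "small_molecule_pool": "smp_c",
        }
    )
    atp: str = "atp_c"
    adp: str = "adp_c"
    pi: str = "pi_c"
    h2o: str = "h2o_c"
    h: str = "h_c"
    biomass_met: str | None = "biomass_c"


def install_composition(
    model: MetabolicModel,
    composition: BiomassComposition,
    mapping: BiomassMapping | None = None,
) -> MetabolicModel:
    """Rebuild the biomass equation and pin NGAM; returns a model copy.

    The biomass reaction drains ``fraction`` grams of each macromolecule
    precursor per gDCW plus GAM mmol of ATP (hydrolysed to ADP + Pi + H),
    and the ATP maintenance reaction is fixed at the NGAM flux.
    """
    from .fba_engine import find_maintenance_reaction

    mapping = mapping or BiomassMapping()
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction")
    new = model.copy()
    biomass = new.reaction(new.biomass_id)
    stoich: dict[str, Fraction] = {}
    for name, fraction in composition.fractions().items():
        if fraction > 0:
            stoich[mapping.precursors[name]] = -Fraction(fraction)
    gam = Fraction(composition.gam)
    if gam > 0:
        stoich[mapping.atp] = -gam
        stoich[mapping.h2o] = stoich.get(mapping.h2o, Fraction(0)) - gam
        stoich[mapping.adp] = gam
        stoich[mapping.pi] = gam
        stoich[mapping.h] = gam
    if mapping.biomass_met is not None:
        stoich[mapping.biomass_met] = Fraction(1)
    missing = sorted(set(stoich) - set(new.metabolite_ids))
    if missing:
        raise KeyError(f"biomass mapping references unknown metabolites: {missing}")
    biomass.stoichiometry = stoich
    maint = new.reaction(find_maintenance_reaction(new))
    maint.lower_bound = composition.ngam
    maint.upper_bound = composition.ngam
    new.validate()
    return new


# ---------------------------------------------------------------------------
# Chemostat phenotype prediction
# ---------------------------------------------------------------------------


@dataclass
class PhenotypePrediction:
    q_glc: float
    mu: float
    q_o2: float
    q_co2: float
    rq: float
    feasible: bool = True

    @classmethod
    def infeasible(cls, q_glc: float) -> "PhenotypePrediction":
        nan = float("nan")
        return cls(q_glc=q_glc, mu=nan, q_o2=nan, q_co2=nan, rq=nan, feasible=False)


def predict_chemostat(
    model: MetabolicModel,
    composition: BiomassComposition,
    q_glc_values: Sequence[float],
    glucose_exchange: str = "EX_glc_e",
    o2_exchange: str = "EX_o2_e",
    co2_exchange: str = "EX_co2_e",
    mapping: BiomassMapping | None = None,
) -> list[PhenotypePrediction]:
    """Predicted mu, qO2, qCO2 and RQ at each fixed glucose uptake rate.

    The composition (with its GAM/NGAM) is installed first; each glucose
    rate is applied as an equality (the measured uptake), growth maximized,
    and the gas exchange rates read from the parsimonious flux vector.
    Infeasible points (e.g. uptake too small to pay NGAM) are reported
    per-point, not raised.
    """
    prepared = install_composition(model, composition, mapping)
    out = []
    for q_glc in q_glc_values:
        point = prepared.copy()
        glc = point.reaction(glucose_exchange)
        glc.lower_bound = glc.upper_bound = -abs(q_glc)
        try:
            solution = pfba(point, "max")
        except Exception:
            out.append(PhenotypePrediction.infeasible(q_glc))
            continue
        q_o2 = -solution.fluxes[o2_exchange]
        q_co2 = solution.fluxes[co2_exchange]
        out.append(
            PhenotypePrediction(
                q_glc=q_glc,
                mu=solution.objective_value,
                q_o2=q_o2,
                q_co2=q_co2,
                rq=q_co2 / q_o2 if q_o2 > 0 else float("nan"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sensitivity scan
# ---------------------------------------------------------------------------

SENSITIVITY_PARAMETERS = MACROMOLECULES + ("ngam",)


def sensitivity_scan(
    model: MetabolicModel,
    parameter: str,
    values: Sequence[float],
    q_glc_grid: Sequence[float],
    composition: BiomassComposition | None = None,
    renormalize: str = "proportional",
    glucose_exchange: str = "EX_glc_e",
    o2_exchange: str = "EX_o2_e",
    mapping: BiomassMapping | None = None,
) -> pd.DataFrame:
    """Growth/oxygen response to one biomass or energy parameter at a time.

    Returns a tidy table (parameter, value, q_glc, mu, q_o2, feasible); mu
    is NaN at infeasible grid points (uptake unable to pay NGAM).
    """
    parameter = parameter.lower()
    if parameter not in SENSITIVITY_PARAMETERS:
        raise ValueError(
            f"parameter must be one of {SENSITIVITY_PARAMETERS}, got {parameter!r}"
        )
    composition = composition or BiomassComposition()
    rows = []
    for value in values:
        if parameter == "ngam":
            varied = replace(composition, ngam=float(value))
        else:
            varied = composition.with_fraction(parameter, float(value), renormalize)
        prepared = install_composition(model, varied, mapping)
        for q_glc in q_glc_grid:
            point = prepared.copy()
            glc = point.reaction(glucose_exchange)
            glc.lower_bound = glc.upper_bound = -abs(q_glc)
            solution = fba(point, "max")
            if solution.optimal:
                sol = pfba(point, "max")
                mu, q_o2, feasible = sol.objective_value, -sol.fluxes[o2_exchange], True
            else:
                mu, q_o2, feasible = float("nan"), float("nan"), False
            rows.append(
                {
                    "parameter": parameter,
                    "value": value,
                    "q_glc": q_glc,
                    "mu": mu,
                    "q_o2": q_o2,
                    "feasible": feasible,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flux-flux correlation
# ---------------------------------------------------------------------------


@dataclass
class FluxComparison:
    r: float
    n: int
    pairs: pd.DataFrame
    unmatched_a: list[str]
    unmatched_b: list[str]


def flux_correlation(
    fluxes_a: Mapping[str, float],
    fluxes_b: Mapping[str, float],
    mapping: Mapping[str, str] | None = None,
) -> FluxComparison:
    """Pearson correlation between two flux vectors over shared reactions.

    ``mapping`` translates keys of ``fluxes_a`` to keys of ``fluxes_b``
    (e.g. model reaction ids to a 13C flux table's ids); without it the
    shared keys are paired directly.  Unmatched keys are reported, never
    silently dropped.
    """
    if mapping is not None:
        pairs = [
            (a_key, b_key)
            for a_key, b_key in mapping.items()
            if a_key in fluxes_a and b_key in fluxes_b
        ]
        matched_a = {a for a, _ in pairs}
        matched_b = {b for _, b in pairs}
    else:
        shared = sorted(set(fluxes_a) & set(fluxes_b))
        pairs = [(key, key) for key in shared]
        matched_a = matched_b = set(shared)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 paired fluxes, got {len(pairs)}")
    a = np.array([fluxes_a[ka] for ka, _ in pairs], dtype=float)
    b = np.array([fluxes_b[kb] for _, kb in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the flux vectors")
    r = float(np.corrcoef(a, b)[0, 1])
    table = pd.DataFrame(
        {"key_a": [ka for ka, _ in pairs], "key_b": [kb for _, kb in pairs], "flux_a": a, "flux_b": b}
    )
    return FluxComparison(
        r=r,
        n=len(pairs),
        pairs=table,
        unmatched_a=sorted(set(fluxes_a) - matched_a),
        unmatched_b=sorted(set(fluxes_b) - matched_b),
    )


# ---------------------------------------------------------------------------
# Expression coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    n_genes: int
    n_genes_expressed: int
    gene_fraction: float
    single_gene: dict[str, int]  # verified / unverified counts
    multi_gene: dict[str, int]
    n_no_gpr: int
    single_gene_fraction: float
    multi_gene_fraction: float


def expression_coverage(
    model: MetabolicModel,
    expressed_genes: Iterable[str],
    mode: str = "gpr",
) -> CoverageReport:
    """Score how well an expression call set covers the model.

    Reports the fraction of model genes expressed and, over non-exchange
    reactions, the verified fraction of single-gene and multi-gene
    reactions.  In the default ``gpr`` mode a reaction is verified when its
    GPR evaluates True with unexpressed genes set False (an OR of isozymes
    needs only one expressed member; an AND complex needs all); the looser
    ``any`` mode requires only one associated gene to be expressed.
    Reactions without a GPR are counted separately.
    """
    if mode not in {"gpr", "any"}:
        raise ValueError(f"mode must be 'gpr' or 'any', got {mode!r}")
    expressed = set(expressed_genes)
    unexpressed = model.genes - expressed
    single = {"verified": 0, "unverified": 0}
    multi = {"verified": 0, "unverified": 0}
    n_no_gpr = 0
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        if rxn.gpr is None:
            n_no_gpr += 1
            continue
        rxn_genes = rxn.gpr.genes()
        if mode == "gpr":
            verified = evaluate_gpr(rxn.gpr, unexpressed)
        else:
            verified = bool(rxn_genes & expressed)
        bucket = single if len(rxn_genes) == 1 else multi
        bucket["verified" if verified else "unverified"] += 1

    def _fraction(bucket: dict[str, int]) -> float:
        total = bucket["verified"] + bucket["unverified"]
        return bucket["verified"] / total if total else float("nan")

    n_expressed = len(model.genes & expressed)
    return CoverageReport(
        n_genes=len(model.genes),
        n_genes_expressed=n_expressed,
        gene_fraction=n_expressed / len(model.genes) if model.genes else float("nan"),
        single_gene=single,
        multi_gene=multi,
        n_no_gpr=n_no_gpr,
        single_gene_fraction=_fraction(single),
        multi_gene_fraction=_fraction(multi),
    )
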