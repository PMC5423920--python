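"""Generators for every input class the pipeline consumes, with ground truth.

Two families of models are generated:

* **Toy networks** (:func:`make_toy_model`) — chain / branched / parallel /
  cycle topologies around a glucose-to-biomass route with a configurable
  carbon yield.  Internal conversions carry balanced elemental formulas (a
  reduced C/H/O/N/P alphabet) by routing the non-assimilated carbon through
  an explicit combustion term (6(1-y) O2 -> CO2 + H2O per glucose), so the
  analytic FBA optimum Z = yield x uptake, the per-gene essentiality
  classes, the minimal pFBA total flux, and the dead-end set are all known
  in closed form and emitted alongside the model.

* **A miniature cell** (:func:`make_cell_model`) — a lumped aerobic
  metabolism with an explicit energy currency (ATP/ADP/Pi), a respiration
  reaction yielding ``ATP_YIELD`` ATP per glucose, one synthesis reaction
  per biomass macromolecule (protein, lipid, RNA, DNA, carbohydrate,
  small-molecule pool) with per-gram glucose/ATP/nitrogen costs, an ATP
  maintenance reaction, and a biomass equation assembled from a
  :class:`~gsmm.physiology.BiomassComposition`.  Growth has the closed form
  mu = (Y_ATP q_glc - NGAM) / (Y_ATP C + B + GAM) with C and B the summed
  glucose and ATP costs of one gram of biomass, which makes chemostat
  emulation and maintenance-fitting exactly invertible.

Chemostat series are generated from the maintenance line
r_ATP = GAM * mu + NGAM with optional Gaussian noise and converted to
exchange rates the cell model reproduces exactly.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr
from .physiology import MACROMOLECULES, BiomassComposition, ChemostatObservation, install_composition

# ---------------------------------------------------------------------------
# The miniature cell model
# ---------------------------------------------------------------------------

#: ATP produced per glucose fully respired (lumped P/O bookkeeping).
ATP_YIELD = 30

#: mmol glucose consumed per gram of macromolecule synthesized (~0.5 g C/g
#: biomass overall); lipid is the most carbon-dense pool.
GLC_COST = {
    "protein": 7,
    "lipid": 9,
    "rna": 7,
    "dna": 7,
    "carbohydrate": 6,
    "small_molecule_pool": 7,
}
#: mmol ATP per gram of macromolecule (polymerization + precursor cost);
#: lipid is deliberately the most expensive pool.
ATP_COST = {
    "protein": 4,
    "lipid": 12,
    "rna": 3,
    "dna": 3,
    "carbohydrate": 2,
    "small_molecule_pool": 3,
}
#: mmol NH4+ per gram (nitrogen content of each pool).
NITROGEN_COST = {
    "protein": 10,
    "lipid": 0,
    "rna": 4,
    "dna": 4,
    "carbohydrate": 0,
    "small_molecule_pool": 2,
}

_CURRENCY = [
    # id, formula, charge (protonation states at pH 7.2)
    ("glc", "C6H12O6", 0),
    ("o2", "O2", 0),
    ("co2", "CO2", 0),
    ("h2o", "H2O", 0),
    ("nh4", "H4N", 1),
    ("h", "H", 1),
]


def glucose_cost_per_gram(composition: BiomassComposition) -> float:
    """C: mmol glucose per gDCW implied by the composition."""
    return sum(composition.fractions()[m] * GLC_COST[m] for m in MACROMOLECULES)


def atp_cost_per_gram(composition: BiomassComposition) -> float:
    """B: growth ATP (mmol/gDCW) in the synthesis reactions, excluding GAM."""
    return sum(composition.fractions()[m] * ATP_COST[m] for m in MACROMOLECULES)


def closed_form_growth(composition: BiomassComposition, q_glc: float, growth_atp: bool = True) -> float:
    """Analytic mu(q_glc) for the cell model; negative means infeasible."""
    c_cost = glucose_cost_per_gram(composition)
    b_cost = atp_cost_per_gram(composition) + composition.gam if growth_atp else 0.0
    return (ATP_YIELD * q_glc - composition.ngam) / (ATP_YIELD * c_cost + b_cost)


def make_cell_model(
    composition: BiomassComposition | None = None,
    growth_atp: bool = True,
    glucose_uptake: float = 10.0,
    with_gprs: bool = True,
    glc_cost: Mapping[str, float] | None = None,
    atp_cost: Mapping[str, float] | None = None,
) -> MetabolicModel:
    """Build the miniature aerobic cell model.

    ``growth_atp=False`` strips every growth-associated ATP term (macro
    synthesis costs and the biomass GAM) and frees the maintenance reaction;
    this is the configuration used to *fit* GAM/NGAM from chemostat data,
    where all growth ATP must appear in the regression slope rather than in
    the stoichiometry.  ``glc_cost`` / ``atp_cost`` override the per-gram
    macromolecule costs (e.g. to construct deliberately cost-degenerate
    compositions).
    """
    if composition is None:
        composition = BiomassComposition()
    if not growth_atp:
        composition = replace(composition, gam=0.0, ngam=0.0)
    glc_cost = {**GLC_COST, **(glc_cost or {})}
    atp_cost = {**ATP_COST, **(atp_cost or {})}

    metabolites = []
    for met_id, formula, charge in _CURRENCY:
        metabolites.append(Metabolite(id=f"{met_id}_e", compartment="e", formula=formula, charge=charge))
        metabolites.append(Metabolite(id=f"{met_id}_c", compartment="c", formula=formula, charge=charge))
    metabolites += [
        Metabolite(id="atp_c", compartment="c", formula="C10H12N5O13P3", charge=-4),
        Metabolite(id="adp_c", compartment="c", formula="C10H12N5O10P2", charge=-3),
        Metabolite(id="pi_c", compartment="c", formula="HO4P", charge=-2),
        Metabolite(id="biomass_c", compartment="c"),
        Metabolite(id="xyl_e", compartment="e", formula="C5H10O5"),
    ]
    metabolites += [
        Metabolite(id=f"{name_id}_c", compartment="c", name=name)
        for name, name_id in (
            ("protein", "protein"),
            ("lipid", "lipid"),
            ("RNA", "rna"),
            ("DNA", "dna"),
            ("carbohydrate", "carbohydrate"),
            ("small-molecule pool", "smp"),
        )
    ]

    def ex(met: str, lb: float, ub: float) -> Reaction:
        return Reaction(id=f"EX_{met}", stoichiometry={met: Fraction(-1)}, lower_bound=lb, upper_bound=ub, subsystem="exchange")

    reactions = [
        ex("glc_e", -glucose_uptake, 0.0),
        ex("o2_e", -1000.0, 0.0),
        ex("co2_e", 0.0, 1000.0),
        ex("h2o_e", -1000.0, 1000.0),
        ex("nh4_e", -1000.0, 0.0),
        ex("h_e", -1000.0, 1000.0),
        ex("biomass_c", 0.0, 1000.0),
        ex("xyl_e", -1000.0, 1000.0),
    ]
    transport_gpr = {"glc": "gGT1 or gGT2"}
    for met_id, _, _ in _CURRENCY:
        reactions.append(
            Reaction(
                id=f"T_{met_id}",
                stoichiometry={f"{met_id}_e": Fraction(-1), f"{met_id}_c": Fraction(1)},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                gpr=parse_gpr(transport_gpr[met_id]) if with_gprs and met_id in transport_gpr else None,
                subsystem="transport",
            )
        )
    reactions.append(
        Reaction(
            id="RESP",
            name="lumped aerobic respiration",
            stoichiometry={
                "glc_c": Fraction(-1),
                "o2_c": Fraction(-6),
                "adp_c": Fraction(-ATP_YIELD),
                "pi_c": Fraction(-ATP_YIELD),
                "h_c": Fraction(-ATP_YIELD),
                "co2_c": Fraction(6),
                "h2o_c": Fraction(6 + ATP_YIELD),
                "atp_c": Fraction(ATP_YIELD),
            },
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=parse_gpr("gRE1 and gRE2") if with_gprs else None,
            subsystem="energy metabolism",
        )
    )
    reactions.append(
        Reaction(
            id="ATPM",
            name="ATP maintenance hydrolysis",
            stoichiometry={
                "atp_c": Fraction(-1),
                "h2o_c": Fraction(-1),
                "adp_c": Fraction(1),
                "pi_c": Fraction(1),
                "h_c": Fraction(1),
            },
            lower_bound=composition.ngam,
            upper_bound=composition.ngam if growth_atp else 1000.0,
            subsystem="energy metabolism",
        )
    )
    precursor_id = {
        "protein": "protein_c",
        "lipid": "lipid_c",
        "rna": "rna_c",
        "dna": "dna_c",
        "carbohydrate": "carbohydrate_c",
        "small_molecule_pool": "smp_c",
    }
    for macro in MACROMOLECULES:
        stoich: dict[str, Fraction] = {"glc_c": -Fraction(glc_cost[macro]), precursor_id[macro]: Fraction(1)}
        if NITROGEN_COST[macro]:
            stoich["nh4_c"] = Fraction(-NITROGEN_COST[macro])
            stoich["h_c"] = stoich.get("h_c", Fraction(0)) + Fraction(NITROGEN_COST[macro])
        if growth_atp and atp_cost[macro]:
            cost = Fraction(atp_cost[macro])
            stoich["atp_c"] = -cost
            stoich["h2o_c"] = -cost
            stoich["adp_c"] = cost
            stoich["pi_c"] = cost
            stoich["h_c"] = stoich.get("h_c", Fraction(0)) + cost
        reactions.append(
            Reaction(
                id=f"SYN_{macro}",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=parse_gpr(f"gSY_{macro}") if with_gprs else None,
                subsystem="biomass precursor synthesis",
            )
        )
    reactions.append(
        Reaction(
            id="BIOMASS",
            name="biomass assembly",
            stoichiometry={"biomass_c": Fraction(1), "protein_c": Fraction(-1)},  # placeholder
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="biomass",
        )
    )
    genes = set()
    for rxn in reactions:
        if rxn.gpr is not None:
            genes |= rxn.gpr.genes()
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_id="BIOMASS",
        id="cell_toy",
    )
    return install_composition(model, composition)


# ---------------------------------------------------------------------------
# Toy network specs
# ---------------------------------------------------------------------------

TOPOLOGIES = ("chain", "branched", "parallel", "cycle")
GPR_PATTERNS = ("single", "isozyme_or", "complex_and", "nested")


@dataclass(frozen=True)
class ToyModelSpec:
    topology: str = "chain"
    n_internal: int = 0  # intermediate 1:1 conversion steps in the backbone
    yields: tuple[float, ...] = (0.5,)  # carbon yield per branch
    gpr_pattern: str = "single"
    seed: int = 0
    uptake: float = 10.0
    planted_gap: bool = False
    planted_imbalance: bool = False
    style: str = "full"  # full = mass-balanced with O2/CO2/H2O bookkeeping

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if self.gpr_pattern not in GPR_PATTERNS:
            raise ValueError(f"gpr_pattern must be one of {GPR_PATTERNS}")
        if self.style not in {"full", "minimal"}:
            raise ValueError("style must be 'full' or 'minimal'")
        if self.n_internal < 0:
            raise ValueError("n_internal must be nonnegative")
        expected = 2 if self.topology == "branched" else 1
        if len(self.yields) != expected:
            raise ValueError(
                f"topology {self.topology!r} takes {expected} yield value(s), got {len(self.yields)}"
            )
        if any(not 0 < y <= 1 for y in self.yields):
            raise ValueError("yields must lie in (0, 1]")
        if self.topology == "branched" and self.yields[0] <= self.yields[1]:
            raise ValueError("branched topology requires yields[0] > yields[1]")
        if self.uptake <= 0:
            raise ValueError("uptake must be positive")


@dataclass
class ToyGroundTruth:
    """Analytic answers emitted alongside a generated toy model."""

    optimum: float  # FBA maximum of the biomass objective
    essentiality: dict[str, str]
    growth_ratio: dict[str, float]  # knockout growth / wild-type growth
    dead_end: set[str] = field(default_factory=set)
    min_total_flux: float | None = None
    imbalanced: dict[str, dict[str, int]] = field(default_factory=dict)


def _conversion(rxn_id: str, substrate: str, product: str, y: Fraction, style: str, gpr=None) -> Reaction:
    """substrate -> y product, combusting the leftover carbon when 'full'."""
    stoich = {substrate: Fraction(-1), product: y}
    if style == "full" and y != 1:
        burn = 6 * (1 - y)
        stoich.update({"o2_c": -burn, "co2_c": burn, "h2o_c": burn})
    return Reaction(id=rxn_id, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0, gpr=gpr)


def make_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, ToyGroundTruth]:
    """Generate a toy network plus its analytic ground truth.

    All internal conversions are elementally balanced in the ``full`` style
    (every intermediate is a C6H12O6 isomer and the non-assimilated carbon
    is combusted); the ``minimal`` style drops the gas/water bookkeeping to
    get networks of <= 8 reactions for solver cross-checks.  Ground truth:
    Z* = yields[0] * uptake, knockout growth from the route structure and
    the GPR truth table, the pFBA-minimal total flux, and the planted
    dead-end / imbalance records.
    """
    hexose = "C6H12O6"
    mets = [
        Metabolite(id="glc_e", compartment="e", formula=hexose),
        Metabolite(id="glc_c", compartment="c", formula=hexose),
        Metabolite(id="pre_c", compartment="c", formula=hexose),
        Metabolite(id="biomass_c", compartment="c"),
    ]
    u = spec.uptake
    reactions = [
        Reaction(id="EX_glc_e", stoichiometry={"glc_e": Fraction(-1)}, lower_bound=-u, upper_bound=0.0),
        Reaction(id="EX_biomass", stoichiometry={"biomass_c": Fraction(-1)}, lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="T_glc", stoichiometry={"glc_e": Fraction(-1), "glc_c": Fraction(1)},
                 lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr("gT")),
        Reaction(id="BIOMASS", stoichiometry={"pre_c": Fraction(-1), "biomass_c": Fraction(1)},
                 lower_bound=0.0, upper_bound=1000.0),
    ]
    # gas/water bookkeeping exists only when some route combusts carbon,
    # otherwise O2/CO2 would be planted dead ends the ground truth not asked for
    needs_gas = spec.style == "full" and any(y < 1 for y in spec.yields)
    if needs_gas:
        for met_id, formula in (("o2", "O2"), ("co2", "CO2"), ("h2o", "H2O")):
            mets.append(Metabolite(id=f"{met_id}_e", compartment="e", formula=formula))
            mets.append(Metabolite(id=f"{met_id}_c", compartment="c", formula=formula))
            lb = -1000.0 if met_id == "o2" else 0.0
            reactions.append(
                Reaction(id=f"EX_{met_id}_e", stoichiometry={f"{met_id}_e": Fraction(-1)}, lower_bound=lb, upper_bound=1000.0)
            )
            sign = 1 if met_id == "o2" else -1  # o2 in, co2/h2o out
            reactions.append(
                Reaction(
                    id=f"T_{met_id}",
                    stoichiometry={f"{met_id}_e": Fraction(-sign), f"{met_id}_c": Fraction(sign)},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                )
            )

    # backbone intermediates (1:1 hexose isomerizations)
    head = "glc_c"
    for k in range(spec.n_internal):
        inter = f"int{k + 1}_c"
        mets.append(Metabolite(id=inter, compartment="c", formula=hexose))
        reactions.append(
            Reaction(id=f"STEP{k + 1}", stoichiometry={head: Fraction(-1), inter: Fraction(1)},
                     lower_bound=0.0, upper_bound=1000.0)
        )
        head = inter

    pattern_rules = {
        "single": "gA",
        "isozyme_or": "gA or gB",
        "complex_and": "gA and gB",
        "nested": "(gA and gB) or gC",
    }
    y_main = Fraction(spec.yields[0]).limit_denominator(10**6)
    route_gprs: dict[str, tuple[str, Fraction]] = {}  # reaction -> (rule, yield)
    if spec.topology == "branched":
        y_low = Fraction(spec.yields[1]).limit_denominator(10**6)
        reactions.append(_conversion("V_hi", head, "pre_c", y_main, spec.style, gpr=parse_gpr("gH")))
        reactions.append(_conversion("V_lo", head, "pre_c", y_low, spec.style, gpr=parse_gpr("gL")))
        route_gprs = {"V_hi": ("gH", y_main), "V_lo": ("gL", y_low)}
    elif spec.topology == "parallel":
        rule = pattern_rules[spec.gpr_pattern]
        reactions.append(_conversion("V_p1", head, "pre_c", y_main, spec.style, gpr=parse_gpr(rule)))
        reactions.append(_conversion("V_p2", head, "pre_c", y_main, spec.style, gpr=parse_gpr(rule)))
        route_gprs = {"V_p1": (rule, y_main), "V_p2": (rule, y_main)}
    else:  # chain, cycle
        rule = pattern_rules[spec.gpr_pattern]
        reactions.append(_conversion("V_syn", head, "pre_c", y_main, spec.style, gpr=parse_gpr(rule)))
        route_gprs = {"V_syn": (rule, y_main)}

    if spec.topology == "cycle":
        # a reversible futile loop threaded through glc_c; pFBA zeroes it
        mets.append(Metabolite(id="cyc1_c", compartment="c", formula=hexose))
        mets.append(Metabolite(id="cyc2_c", compartment="c", formula=hexose))
        for rxn_id, (a, b) in (
            ("CYC1", ("glc_c", "cyc1_c")),
            ("CYC2", ("cyc1_c", "cyc2_c")),
            ("CYC3", ("cyc2_c", "glc_c")),
        ):
            reactions.append(
                Reaction(id=rxn_id, stoichiometry={a: Fraction(-1), b: Fraction(1)},
                         lower_bound=-1000.0, upper_bound=1000.0)
            )

    truth = ToyGroundTruth(optimum=float(y_main) * u, essentiality={}, growth_ratio={})

    if spec.planted_gap:
        mets.append(Metabolite(id="orphan_c", compartment="c", formula=hexose))
        reactions.append(
            Reaction(id="DEAD_orphan", stoichiometry={"glc_c": Fraction(-1), "orphan_c": Fraction(1)},
                     lower_bound=0.0, upper_bound=1000.0)
        )
        truth.dead_end = {"orphan_c"}
    if spec.planted_imbalance:
        # a 1 -> 6 hexose "duplication": residual is 5 extra hexoses
        reactions.append(
            Reaction(id="BAD_burn", stoichiometry={"glc_c": Fraction(-1), "pre_c": Fraction(6)},
                     lower_bound=0.0, upper_bound=0.0)
        )
        truth.imbalanced = {"BAD_burn": {"C": 30, "H": 60, "O": 30}}

    genes = set()
    for rxn in reactions:
        if rxn.gpr is not None:
            genes |= rxn.gpr.genes()

    # knockout growth from route structure: available branches after deletion
    for gene in sorted(genes):
        if gene == "gT":
            mu_ko = 0.0
        else:
            best = Fraction(0)
            for rxn_id, (rule, branch_yield) in route_gprs.items():
                if parse_gpr(rule).evaluate({gene}):
                    best = max(best, branch_yield)
            mu_ko = float(best) * u
        ratio = mu_ko / truth.optimum
        truth.growth_ratio[gene] = ratio
        truth.essentiality[gene] = (
            "essential" if mu_ko == 0 else "non_essential" if ratio >= 1 - 1e-12 else "partially_essential"
        )

    # pFBA-minimal total flux: backbone chain + combustion bookkeeping
    y = float(y_main)
    per_uptake = 3.0 + 2.0 * y + spec.n_internal
    if spec.style == "full":
        per_uptake += 36.0 * (1.0 - y)
    truth.min_total_flux = per_uptake * u

    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_id="BIOMASS",
        id=f"toy_{spec.topology}_{spec.seed}",
    )
    return model, truth


def random_toy_spec(seed: int, style: str = "full", allow_gaps: bool = True) -> ToyModelSpec:
    """A randomized but always-valid ToyModelSpec (pure function of seed)."""
    rng = np.random.default_rng(seed)
    topology = TOPOLOGIES[rng.integers(len(TOPOLOGIES))]
    if topology == "branched":
        y_hi = round(float(rng.uniform(0.5, 1.0)), 3)
        y_lo = round(float(rng.uniform(0.1, 0.9)) * y_hi, 3) or 0.1
        yields: tuple[float, ...] = (y_hi, y_lo)
    else:
        yields = (round(float(rng.uniform(0.2, 1.0)), 3),)
    return ToyModelSpec(
        topology=topology,
        n_internal=int(rng.integers(0, 3)) if style == "full" else 0,
        yields=yields,
        gpr_pattern=GPR_PATTERNS[rng.integers(len(GPR_PATTERNS))],
        seed=seed,
        uptake=round(float(rng.uniform(1.0, 20.0)), 3),
        planted_gap=bool(allow_gaps and rng.random() < 0.3),
        style=style,
    )


# ---------------------------------------------------------------------------
# Chemostat emulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemostatSimSpec:
    true_gam: float = 20.4  # mmol ATP/gDCW
    true_ngam: float = 2.52  # mmol ATP/gDCW/h
    mu_grid: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)
    noise_sd: float = 0.0  # Gaussian noise on r_ATP, mmol ATP/gDCW/h
    seed: int = 0

    def __post_init__(self) -> None:
        if any(mu <= 0 for mu in self.mu_grid):
            raise ValueError("all growth rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_chemostat(
    spec: ChemostatSimSpec,
    composition: BiomassComposition | None = None,
) -> tuple[list[ChemostatObservation], pd.DataFrame]:
    """Emulate steady-state chemostat measurements from the maintenance line.

    For each growth rate mu the true maintenance ATP r_ATP = GAM*mu + NGAM
    (plus optional Gaussian noise) is converted to the glucose/O2/CO2
    exchange rates the no-growth-ATP cell model implies, so that pinning the
    observed rates in that model and maximizing maintenance ATP recovers the
    noisy r_ATP exactly.  Noise-free generation lies exactly on the line.
    Returns the observations and a tidy table including the true r_ATP.
    """
    composition = composition or BiomassComposition()
    fit_composition = replace(composition, gam=0.0, ngam=0.0)
    c_cost = glucose_cost_per_gram(fit_composition)
    rng = np.random.default_rng(spec.seed)
    observations = []
    rows = []
    for mu in spec.mu_grid:
        r_true = spec.true_gam * mu + spec.true_ngam
        r_obs = r_true + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        respiration = r_obs / ATP_YIELD
        q_glc = respiration + mu * c_cost
        q_gas = 6.0 * respiration
        observations.append(
            ChemostatObservation(
                dilution_rate=mu,
                rates={"EX_glc_e": -q_glc, "EX_o2_e": -q_gas, "EX_co2_e": q_gas},
            )
        )
        rows.append(
            {"mu": mu, "q_glc": q_glc, "q_o2": q_gas, "q_co2": q_gas,
             "r_atp_true": r_true, "r_atp_observed": r_obs}
        )
    return observations, pd.DataFrame(rows)


def make_maintenance_fit_model(composition: BiomassComposition | None = None) -> MetabolicModel:
    """The cell model configured for GAM/NGAM fitting (no growth ATP)."""
    return make_cell_model(composition=composition, growth_atp=False, glucose_uptake=1000.0)


# ---------------------------------------------------------------------------
# Perturbed fluxes and expression calls
# ---------------------------------------------------------------------------


def perturb_fluxes(fluxes: Mapping[str, float], sd: float, seed: int) -> dict[str, float]:
    """Add iid Gaussian noise to a flux vector (sd = 0 is the identity)."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    keys = list(fluxes)
    noise = rng.normal(0.0, sd, size=len(keys)) if sd > 0 else np.zeros(len(keys))
    return {key: float(fluxes[key]) + float(eps) for key, eps in zip(keys, noise)}


def simulate_expression(model: MetabolicModel, p_expressed: float, seed: int) -> set[str]:
    """Bernoulli(p) expression call per model gene, seeded and reproducible."""
    if not 0 <= p_expressed <= 1:
        raise ValueError("p_expressed must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    draws = rng.random(len(genes))
    return {gene for gene, draw in zip(genes, draws) if draw < p_expressed}
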