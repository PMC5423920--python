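# Methods

This note documents the models, conventions and numerical choices behind
`gsmm`, what the synthetic-data generators do and do not emulate, and the
known limitations.

## FBA core

FBA solves `max/min cᵀv` subject to `S v = 0`, `lb ≤ v ≤ ub` through scipy's
HiGHS interface with primal/dual feasibility tolerances of 1e-9, presolve on,
and single-threaded deterministic options; post-hoc audits assert
`max|S v| ≤ 1e-7` and per-reaction bound violations ≤ 1e-7 on every optimal
solution. Infeasible and unbounded problems are reported through the
solution status, never as a silent zero. Reversible reactions default to
bounds of −1000/1000 mmol/gDCW/h, kept as literal sentinels rather than ±∞
(the convention of published reconstructions); irreversible reactions have
lb ≥ 0.

Only the objective value Z is treated as canonical: FBA flux vectors are
degenerate at the optimum, so every flux-level quantity downstream (gas
exchange rates, flux correlations) is read from pFBA. pFBA splits each
reaction into nonnegative forward/reverse halves and minimizes their sum
subject to the original constraints plus the optimum pinned as the one-sided
bound `Z ≥ Z*(1 − 1e-9)` — an inequality rather than an equality for
numerical robustness. The split formulation (as opposed to an absolute-value
reformulation with free variables) was chosen because it keeps the problem a
plain LP with box bounds; the two are equivalent at the optimum.

## GPR rules

GPR rules are Boolean trees over gene identifiers with `and` binding tighter
than `or` and parentheses overriding — the dominant convention in published
reconstructions. Parsing normalizes the tree: nested nodes of the same
operator are flattened and duplicate children dropped, making
parse → print → parse a fixed point. A gene deletion sets `lb = ub = 0` on
every reaction whose rule evaluates False with the deleted genes absent;
reactions without a rule (spontaneous or orphan reactions) are never
disabled, the standard convention.

## Balance checking

Reaction residuals are computed per element as Σ coefficient × atom count
from Hill-style formulas (one- or two-letter element symbols with optional
integer counts, no parentheses), with charge treated as one extra
pseudo-element so a single exact-rational code path covers both mass and
charge. A reaction is `balanced` iff every residual is exactly zero. Three
situations are `undeterminable` rather than imbalanced: exchange reactions
(boundary by construction), any participant with an empty or unparseable
formula, and any participant carrying a generic R/X group. Biomass-style
lumped reactions fall out of the same rule — their pseudo-metabolite
precursors (protein, lipid, ...) carry no formula, because mass-fraction
lumps are not molecular species; they are therefore exempt from balance
enforcement by construction rather than by a special case.

## Dead-end metabolites

Two definitions are provided. The default ("root") definition is a
direction-aware scan: a metabolite is non-producible when no reaction has it
with (positive coefficient and ub > 0) or (negative coefficient and lb < 0),
symmetrically for consumption; the dead-end set is the union. The
`transitive=True` mode propagates blockage by two independent reachability
fixpoints — producible metabolites expand from boundary inflows one reaction
direction at a time once all of that direction's substrates are producible,
and consumable metabolites symmetrically contract toward boundary outflows.
The two questions are deliberately not coupled, mirroring the LP oracle
(maximize an auxiliary drain or supply flux for one metabolite at a time),
against which the transitive mode is verified on randomized generated
networks.

Known limitation: reachability relaxations cannot see stoichiometric
coupling. A conserved currency pool (e.g. ATP/ADP with no net source, as in
the bundled cell model) is non-producible in the strict LP sense even though
every member has producers and consumers; the transitive mode additionally
over-reports metabolites whose only consumers recycle through such a pool.
The root definition is therefore the default, and transitive results on
networks with conserved moieties should be read as "strictly blocked under
independent disposal", not as reconstruction errors.

## Essentiality and growth screens

Deletion phenotypes follow the three-class convention with the printed
"zero growth" and "wild-type growth" boundaries made numerically explicit:
essential when μ_ko < ε_zero (default 1e-6 h⁻¹), non-essential when
μ_ko ≥ (1 − δ)·μ_wt (default δ = 1e-3), partially essential in between. Both
thresholds are configurable; classification depends only on objective
values, so it is stable to alternate optima and reaction order.

Growth-source screens open one candidate at a time: for a carbon screen
every other exchange whose metabolite contains carbon (computed from parsed
formulas, never guessed — unparseable candidates are flagged
`unscreenable`) has its uptake closed while the mineral background and the
fixed nitrogen source stay open; nitrogen screens are symmetric with glucose
as the sole carbon source. Because candidate uptake rates are rarely
reported, the default normalization supplies carbon at a 6-carbon-equivalent
reference rate (rate × 6 / n_C), configurable to a fixed molar rate;
nitrogen candidates use the fixed molar rate. A source is growth-supporting
when predicted growth exceeds ε_zero.

## Maintenance energetics

The total maintenance ATP of one chemostat condition, r_ATP, is the maximal
flux through the ATP hydrolysis maintenance reaction with the measured
exchange rates and the growth rate pinned. Pins are exact equalities by
default; a relative relaxation band (e.g. ±2%) is available for real data
with measurement error, but note that the LP then sits at the favorable edge
of the band, scaling r_ATP by exactly (1 + band) on consistent data — which
is why the default is 0. On infeasible pins, each rate is relaxed in turn to
name a binding constraint.

GAM and NGAM are the slope and intercept of the ordinary least-squares fit
of r_ATP on μ. The extraction model must carry no growth-associated ATP in
its stoichiometry (no GAM term in biomass, no synthesis ATP costs),
otherwise that ATP is paid inside the model and vanishes from the regression
slope; `make_maintenance_fit_model()` provides exactly this configuration.
A negative fitted NGAM is returned with a warning rather than clamped. With
two or more distinct dilution rates the fit is exact on noise-free data; all
growth rates equal is a singular design and an error.

## Biomass composition and sensitivity

`BiomassComposition` holds the macromolecular mass fractions (g/gDCW) of
protein, lipid, RNA, DNA, carbohydrate and a small-molecule pool plus GAM
and NGAM. The defaults (0.42 / 0.112 / 0.116 / 0.0055 / 0.319 / 0.0275,
GAM 20.4 mmol ATP/gDCW, NGAM 2.52 mmol ATP/gDCW/h) sit at the midpoints of
the composition ranges scanned by the sensitivity analysis and sum exactly
to 1 g/gDCW. Installing a composition rebuilds the biomass reaction (each
fraction drains its precursor pseudo-metabolite, GAM hydrolyses ATP to
ADP + Pi + H) and fixes the maintenance reaction at NGAM.

The sensitivity scan varies exactly one parameter at a time — a
macromolecule fraction over its physiological range or NGAM — and
renormalizes the remaining fractions so the total stays 1 g/gDCW. How to
renormalize is a genuinely open choice; proportional rescaling of
all other fractions is the default (least informative), with an
absorb-into-carbohydrate alternative behind a flag. Scans report μ and qO₂
per glucose-uptake grid point, with infeasible points (uptake below the NGAM
break-even) reported as NaN rather than raised.

## Transcriptome coverage

Gene coverage is the expressed fraction of model genes. Reaction
verification (over non-exchange reactions, with GPR-less reactions counted
separately) defaults to GPR evaluation — expressed genes True, unexpressed
False, so an OR of isozymes needs one expressed member and an AND complex
needs all — because "a reaction with gene expression" is ambiguous between
that and "any associated gene expressed"; the looser `any` mode is available
behind a flag.

## Synthetic data: what it emulates and what it does not

The toy networks (chain / branched / parallel / cycle around a
glucose-to-biomass route) are built so every quantity the pipeline computes
has a closed form: the FBA optimum is yield × uptake, knockout growth
follows from the route structure and the GPR truth table, the pFBA-minimal
total flux is a short formula, and QC defects (an orphan metabolite, an
unbalanced reaction) are planted explicitly. Internal conversions are
elementally balanced by treating every backbone intermediate as a hexose
isomer and combusting the non-assimilated carbon (6(1−y) O₂ → CO₂ + H₂O per
glucose); a `minimal` style drops the gas bookkeeping to keep networks at
≤ 8 reactions for exhaustive vertex-enumeration cross-checks.

The miniature cell model adds an explicit energy currency: lumped
respiration yields 30 ATP per glucose (a rounded P/O bookkeeping), each
macromolecule costs 6–9 mmol glucose, 2–12 mmol ATP and 0–10 mmol NH₄⁺ per
gram (lipid deliberately the most expensive pool, protein the most
nitrogen-rich), giving the closed-form growth rate
μ = (30·q_glc − NGAM) / (30·C + B + GAM) with C ≈ 6.9 mmol glucose and
B ≈ 4.1 mmol ATP per gDCW. At the five glucose uptake rates 0.478–1.846
mmol/gDCW/h this yields μ between 0.05 and 0.23 h⁻¹ — the dilution-rate
range of glucose-limited yeast chemostats. Chemostat series are generated by
inverting that energy balance: given μ and r_ATP = GAM·μ + NGAM (+ Gaussian
noise on r_ATP), the implied glucose/O₂/CO₂ exchange rates are emitted, so
the fitting pipeline recovers the generating parameters exactly at zero
noise, and OLS sampling theory applies at positive noise.

What the generators do **not** capture, and hence what passing tests do not
show about real reconstructions: overflow metabolism and by-product
secretion (the cell model is fully respiratory, RQ ≡ 1), alternate optimal
flux modes at genome scale, compartmentalized energy coupling and proton
gradients, measurement error structure beyond iid Gaussian noise on r_ATP,
incomplete or wrong GPR annotations, and the sheer degeneracy of
2000-reaction networks. Reproducing a published model's headline counts and
screens additionally requires that model's own tables, which are consumed
through the same `read_model_tables`/`read_sbml_subset` entry points.

All generators are pure functions of (spec, seed) with one explicit
`numpy.random.default_rng` per call; no global random state.

## Problem sizes and runtime

The bundled checks use 100 random toy networks for the solver and gap
oracles, 200 replicates of 50-point chemostat series (σ = 0.1) for the
noisy maintenance fit, a 5 × 9 NGAM × uptake grid for the monotonicity scan,
and ≤ 8-reaction networks for vertex enumeration — sizes at which exhaustive
oracles are exact and the full acceptance run completes in well under a
minute on one CPU.

## Known limitations

* No loopless FBA or FVA; thermodynamically infeasible cycles are only
  suppressed by the pFBA parsimony criterion.
* Formula grammar has no parentheses or hydrate dots; such formulas are
  flagged unparseable (and the reactions undeterminable) rather than parsed.
* SBML support is a Level 3 core + FBC v2 subset (species, reactions,
  bounds, gene associations, objective, charge/formula, notes); kinetic
  laws, rules and events are out of scope. Stoichiometries and bounds travel
  as IEEE doubles, exact for the dyadic rationals the generators emit.
* The transitive gap mode over-reports on conserved currency pools (see
  above).
* Double-gene deletions and quantitative growth matching per carbon source
  are not implemented.
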