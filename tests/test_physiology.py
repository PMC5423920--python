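"""Maintenance fitting, chemostat prediction, sensitivity, correlation, coverage."""

import math
from fractions import Fraction

import numpy as np
import pytest

from gsmm import (
    BiomassComposition,
    ChemostatObservation,
    ChemostatSimSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    expression_coverage,
    fit_maintenance,
    flux_correlation,
    make_cell_model,
    parse_gpr,
    perturb_fluxes,
    pfba,
    predict_chemostat,
    sensitivity_scan,
    simulate_chemostat,
)
from gsmm.synthetic_data import closed_form_growth

CHEMOSTAT_Q_GLC = [0.478, 0.692, 0.942, 1.294, 1.846]


class TestFitMaintenance:
    def test_noise_free_recovery_is_exact(self, fit_model):
        observations, _ = simulate_chemostat(ChemostatSimSpec(noise_sd=0.0))
        fit = fit_maintenance(observations, fit_model)
        assert fit.gam == pytest.approx(20.4, abs=1e-9)
        assert fit.ngam == pytest.approx(2.52, abs=1e-9)
        assert np.max(np.abs(fit.residuals)) < 1e-9

    def test_two_point_exact_line(self, fit_model):
        observations, table = simulate_chemostat(ChemostatSimSpec(mu_grid=(0.05, 0.10)))
        assert list(table["r_atp_true"]) == pytest.approx([3.54, 4.56])
        fit = fit_maintenance(observations, fit_model)
        assert (fit.gam, fit.ngam) == (pytest.approx(20.4, abs=1e-9), pytest.approx(2.52, abs=1e-9))

    def test_noisy_recovery_within_sampling_error(self, fit_model):
        spec = ChemostatSimSpec(mu_grid=tuple(np.linspace(0.05, 0.25, 20)), noise_sd=0.1, seed=7)
        observations, _ = simulate_chemostat(spec)
        fit = fit_maintenance(observations, fit_model)
        mu = fit.mu
        sxx = np.sum((mu - mu.mean()) ** 2)
        sigma = 0.1
        se_slope = sigma / math.sqrt(sxx)
        se_intercept = sigma * math.sqrt(1 / len(mu) + mu.mean() ** 2 / sxx)
        assert abs(fit.gam - 20.4) < 3 * se_slope
        assert abs(fit.ngam - 2.52) < 3 * se_intercept

    def test_degenerate_designs_rejected(self, fit_model):
        observations, _ = simulate_chemostat(ChemostatSimSpec(mu_grid=(0.1,)))
        with pytest.raises(ValueError):
            fit_maintenance(observations, fit_model)
        same_mu = [observations[0], observations[0]]
        with pytest.raises(ValueError, match="singular"):
            fit_maintenance(same_mu, fit_model)

    def test_negative_intercept_warned_but_returned(self, fit_model):
        observations, _ = simulate_chemostat(
            ChemostatSimSpec(true_gam=20.0, true_ngam=-0.5, mu_grid=(0.1, 0.2))
        )
        with pytest.warns(UserWarning, match="negative"):
            fit = fit_maintenance(observations, fit_model)
        assert fit.ngam == pytest.approx(-0.5, abs=1e-9)


class TestPredictChemostat:
    def test_zero_uptake_infeasible_with_positive_ngam(self, cell_model, default_composition):
        point = predict_chemostat(cell_model, default_composition, [0.0])[0]
        assert point.feasible is False and math.isnan(point.mu)

    def test_zero_uptake_zero_growth_without_ngam(self, cell_model):
        free = BiomassComposition(ngam=0.0)
        point = predict_chemostat(cell_model, free, [0.0])[0]
        assert point.feasible and point.mu == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_energy_balance(self, cell_model, default_composition):
        predictions = predict_chemostat(cell_model, default_composition, CHEMOSTAT_Q_GLC)
        for point in predictions:
            assert point.mu == pytest.approx(
                closed_form_growth(default_composition, point.q_glc), abs=1e-7
            )

    def test_growth_strictly_increases_with_uptake(self, cell_model, default_composition):
        mus = [p.mu for p in predict_chemostat(cell_model, default_composition, CHEMOSTAT_Q_GLC)]
        assert all(b > a for a, b in zip(mus, mus[1:]))

    def test_fully_respiratory_quotient_is_one(self, cell_model, default_composition):
        for point in predict_chemostat(cell_model, default_composition, [1.0]):
            assert point.rq == pytest.approx(1.0, abs=1e-6)
            assert point.q_o2 > 0 and point.q_co2 > 0


class TestSensitivityScan:
    def test_growth_monotone_decreasing_in_ngam(self, cell_model):
        table = sensitivity_scan(cell_model, "ngam", [1.26, 3.78], [0.5, 1.0, 2.0])
        pivot = table.pivot(index="q_glc", columns="value", values="mu")
        assert (pivot[3.78] < pivot[1.26]).all()
        q_o2 = table.pivot(index="q_glc", columns="value", values="q_o2")
        assert (q_o2[3.78] > q_o2[1.26]).all()

    def test_lipid_increase_lowers_growth(self, cell_model):
        table = sensitivity_scan(cell_model, "lipid", [0.062, 0.162], [1.0])
        mu_by_value = table.set_index("value")["mu"]
        assert mu_by_value[0.162] < mu_by_value[0.062]

    def test_cost_degenerate_protein_swap_leaves_growth_unchanged(self):
        """If protein and carbohydrate cost the same, trading one for the
        other (absorb-into-carbohydrate renormalization) cannot move mu."""
        model = make_cell_model(
            glc_cost={"protein": 6, "carbohydrate": 6},
            atp_cost={"protein": 2, "carbohydrate": 2},
        )
        table = sensitivity_scan(
            model, "protein", [0.37, 0.42, 0.47], [1.0], renormalize="carbohydrate"
        )
        mus = table["mu"].to_numpy()
        assert np.ptp(mus) < 1e-9

    def test_mu_continuous_along_uptake_grid(self, cell_model):
        grid = np.linspace(0.2, 2.0, 10)
        table = sensitivity_scan(cell_model, "ngam", [2.52], grid)
        mus = table["mu"].to_numpy()
        steps = np.diff(mus)
        # linear response: adjacent steps equal within solver tolerance
        assert np.ptp(steps) < 1e-6

    def test_overfull_fraction_rejected(self, cell_model):
        with pytest.raises(ValueError):
            sensitivity_scan(cell_model, "protein", [1.0], [1.0])

    def test_unknown_parameter_rejected(self, cell_model):
        with pytest.raises(ValueError):
            sensitivity_scan(cell_model, "ash", [0.1], [1.0])


class TestFluxCorrelation:
    def test_identity_and_sign_flip(self):
        v = {"R1": 1.0, "R2": -2.0, "R3": 3.5, "R4": 0.0}
        assert flux_correlation(v, v).r == pytest.approx(1.0)
        neg = {k: -x for k, x in v.items()}
        assert flux_correlation(v, neg).r == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_noisy_pfba(self, chain):
        model, _ = chain
        fluxes = pfba(model).fluxes
        noisy = perturb_fluxes(fluxes, sd=0.5, seed=42)
        result = flux_correlation(fluxes, noisy)
        a = np.array([fluxes[k] for k in result.pairs["key_a"]])
        b = np.array([noisy[k] for k in result.pairs["key_b"]])
        textbook = np.sum((a - a.mean()) * (b - b.mean())) / math.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert result.r == pytest.approx(textbook, abs=1e-12)
        assert abs(result.r - textbook) < 0.05

    def test_symmetry_and_affine_invariance(self):
        a = {"R1": 1.0, "R2": 4.0, "R3": -3.0, "R4": 2.0}
        b = {"R1": 0.5, "R2": 3.1, "R3": -2.0, "R4": 2.2}
        assert flux_correlation(a, b).r == pytest.approx(flux_correlation(b, a).r)
        scaled = {k: 3.0 * x + 7.0 for k, x in b.items()}
        assert flux_correlation(a, scaled).r == pytest.approx(flux_correlation(a, b).r)

    def test_mapping_and_unmatched_reporting(self):
        a = {"glycolysis_1": 1.0, "tca_1": 2.0, "ppp_1": 3.0, "orphan": 9.0}
        b = {"v1": 1.1, "v2": 1.9, "v3": 3.2, "extra": 0.0}
        result = flux_correlation(a, b, mapping={"glycolysis_1": "v1", "tca_1": "v2", "ppp_1": "v3"})
        assert result.n == 3
        assert result.unmatched_a == ["orphan"]
        assert result.unmatched_b == ["extra"]

    def test_too_few_pairs_and_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            flux_correlation({"R1": 1.0, "R2": 2.0}, {"R1": 1.0, "R2": 2.0})
        flat = {"R1": 1.0, "R2": 1.0, "R3": 1.0}
        varying = {"R1": 1.0, "R2": 2.0, "R3": 3.0}
        with pytest.raises(ValueError, match="variance"):
            flux_correlation(flat, varying)


def _coverage_testbed():
    mets = [Metabolite(id="a", compartment="c"), Metabolite(id="b", compartment="c")]
    ab = {"a": Fraction(-1), "b": Fraction(1)}
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a": Fraction(-1)}, lower_bound=-1, upper_bound=1),
        Reaction(id="EX_b", stoichiometry={"b": Fraction(-1)}, lower_bound=0, upper_bound=1),
        Reaction(id="R1", stoichiometry=dict(ab), gpr=parse_gpr("g1")),
        Reaction(id="R2", stoichiometry=dict(ab), gpr=parse_gpr("g1 or g2")),
        Reaction(id="R3", stoichiometry=dict(ab), gpr=parse_gpr("g3 and g4")),
        Reaction(id="R4", stoichiometry=dict(ab)),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes={"g1", "g2", "g3", "g4"})


class TestExpressionCoverage:
    def test_gene_fraction(self):
        report = expression_coverage(_coverage_testbed(), {"g1", "g2", "g3"})
        assert report.gene_fraction == pytest.approx(0.75)

    def test_or_rule_verified_by_single_isozyme(self):
        report = expression_coverage(_coverage_testbed(), {"g2"})
        assert report.multi_gene["verified"] == 1  # R2 via g2; R3 broken

    def test_and_rule_needs_every_subunit(self):
        report = expression_coverage(_coverage_testbed(), {"g1", "g2", "g3"})
        assert report.multi_gene == {"verified": 1, "unverified": 1}  # R3 misses g4
        relaxed = expression_coverage(_coverage_testbed(), {"g1", "g2", "g3"}, mode="any")
        assert relaxed.multi_gene == {"verified": 2, "unverified": 0}

    def test_partition_is_exhaustive_and_disjoint(self, cell_model):
        from gsmm import simulate_expression

        report = expression_coverage(cell_model, simulate_expression(cell_model, 0.6, 5))
        n_internal = sum(1 for r in cell_model.reactions if not r.is_exchange)
        classified = (
            report.single_gene["verified"] + report.single_gene["unverified"]
            + report.multi_gene["verified"] + report.multi_gene["unverified"]
            + report.n_no_gpr
        )
        assert classified == n_internal
        for fraction in (report.gene_fraction, report.single_gene_fraction, report.multi_gene_fraction):
            assert 0.0 <= fraction <= 1.0

    def test_superset_of_model_genes_allowed(self):
        report = expression_coverage(_coverage_testbed(), {"g1", "g2", "g3", "g4", "foreign"})
        assert report.gene_fraction == 1.0
        assert report.single_gene_fraction == 1.0 and report.multi_gene_fraction == 1.0
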