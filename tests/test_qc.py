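"""Formula parsing, mass/charge balance, dead-end detection, model summary."""

from fractions import Fraction

import pytest

from gsmm import (
    FormulaError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelSpec,
    check_model_balance,
    check_reaction_balance,
    find_dead_end_metabolites,
    make_toy_model,
    parse_formula,
    summarize_model,
)
from gsmm.model_qc import is_generic_formula

from .oracles import charwalk_formula, lp_producible


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula",
        ["H2O", "C6H12O6", "C10H12N5O13P3", "C10H12N5O10P2", "HO4P", "H4N", "H", "O2", "Fe2O3"],
    )
    def test_matches_character_walk_oracle(self, formula):
        assert parse_formula(formula) == charwalk_formula(formula)

    def test_count_defaults_to_one(self):
        assert parse_formula("CHO") == {"C": 1, "H": 1, "O": 1}

    @pytest.mark.parametrize("bad", ["", "c6h12", "C6-H12", "6C", "C6 H12"])
    def test_illegal_formulas_raise(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_generic_pseudo_elements_accepted_but_flagged(self):
        counts = parse_formula("C10H18R2X")
        assert counts["R"] == 2 and counts["X"] == 1
        assert is_generic_formula(counts)
        assert not is_generic_formula(parse_formula("H2O"))


def _hexokinase_fixture(drop_proton=False):
    """glc + ATP -> G6P + ADP (+ H): a classic charge/proton test case."""
    mets = {
        "glc": Metabolite(id="glc", compartment="c", formula="C6H12O6", charge=0),
        "atp": Metabolite(id="atp", compartment="c", formula="C10H12N5O13P3", charge=-4),
        "g6p": Metabolite(id="g6p", compartment="c", formula="C6H11O9P", charge=-2),
        "adp": Metabolite(id="adp", compartment="c", formula="C10H12N5O10P2", charge=-3),
        "h": Metabolite(id="h", compartment="c", formula="H", charge=1),
    }
    stoich = {"glc": Fraction(-1), "atp": Fraction(-1), "g6p": Fraction(1), "adp": Fraction(1), "h": Fraction(1)}
    if drop_proton:
        del stoich["h"]
    return Reaction(id="HEX", stoichiometry=stoich), mets


class TestReactionBalance:
    def test_balanced_phosphorylation(self):
        rxn, mets = _hexokinase_fixture()
        report = check_reaction_balance(rxn, mets)
        assert report.status == "balanced"
        assert report.element_residuals == {} and report.charge_residual == 0

    def test_missing_proton_detected(self):
        rxn, mets = _hexokinase_fixture(drop_proton=True)
        report = check_reaction_balance(rxn, mets)
        assert report.status == "imbalanced"
        assert report.element_residuals == {"H": Fraction(-1)}
        assert report.charge_residual == Fraction(-1)

    def test_empty_formula_is_undeterminable(self):
        rxn, mets = _hexokinase_fixture()
        mets["g6p"].formula = ""
        assert check_reaction_balance(rxn, mets).status == "undeterminable"

    def test_generic_group_is_undeterminable(self):
        rxn, mets = _hexokinase_fixture()
        mets["g6p"].formula = "C6H11O9PR"
        assert check_reaction_balance(rxn, mets).status == "undeterminable"

    def test_exchange_is_boundary_undeterminable(self, chain):
        model, _ = chain
        table = {m.id: m for m in model.metabolites}
        report = check_reaction_balance(model.reaction("EX_glc_e"), table)
        assert report.status == "undeterminable"

    def test_missing_metabolite_named(self):
        rxn, mets = _hexokinase_fixture()
        del mets["adp"]
        with pytest.raises(KeyError, match="adp"):
            check_reaction_balance(rxn, mets)

    def test_order_independence(self):
        rxn, mets = _hexokinase_fixture()
        reversed_rxn = Reaction(id="HEX", stoichiometry=dict(reversed(list(rxn.stoichiometry.items()))))
        a = check_reaction_balance(rxn, mets)
        b = check_reaction_balance(reversed_rxn, mets)
        assert (a.status, a.element_residuals, a.charge_residual) == (
            b.status, b.element_residuals, b.charge_residual,
        )

    def test_planted_imbalance_flagged_exactly(self):
        model, truth = make_toy_model(ToyModelSpec(planted_imbalance=True))
        reports = {r.reaction_id: r for r in check_model_balance(model)}
        for rxn_id, residuals in truth.imbalanced.items():
            assert reports[rxn_id].status == "imbalanced"
            assert {e: int(v) for e, v in reports[rxn_id].element_residuals.items()} == residuals
        # everything else with full formulas is balanced; boundary and
        # biomass-style reactions are undeterminable, never imbalanced
        for rxn_id, report in reports.items():
            if rxn_id not in truth.imbalanced:
                assert report.status in {"balanced", "undeterminable"}


class TestDeadEnds:
    def test_unconsumed_chain_end(self):
        mets = [Metabolite(id=x, compartment="c") for x in "ABC"]
        rxns = [
            Reaction(id="EX_A", stoichiometry={"A": Fraction(-1)}, lower_bound=-10, upper_bound=0),
            Reaction(id="AB", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}, lower_bound=0, upper_bound=10),
            Reaction(id="BC", stoichiometry={"B": Fraction(-1), "C": Fraction(1)}, lower_bound=0, upper_bound=10),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        report = find_dead_end_metabolites(model)
        assert "C" in report.no_consumption and "C" not in report.no_production

    def test_reversibility_rescues_both_directions(self):
        mets = [Metabolite(id=x, compartment="c") for x in "AB"]
        rxns = [
            Reaction(id="EX_A", stoichiometry={"A": Fraction(-1)}, lower_bound=-10, upper_bound=10),
            Reaction(id="AB", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}, lower_bound=-10, upper_bound=10),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        assert find_dead_end_metabolites(model).dead_end == set()
        for met in "AB":
            assert lp_producible(model, met, "production")
            assert lp_producible(model, met, "consumption")

    def test_fully_blocked_reaction_orphans_metabolite(self):
        mets = [Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")]
        rxns = [
            Reaction(id="EX_A", stoichiometry={"A": Fraction(-1)}, lower_bound=-10, upper_bound=10),
            Reaction(id="AB", stoichiometry={"A": Fraction(-1), "B": Fraction(1)}, lower_bound=0, upper_bound=0),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        report = find_dead_end_metabolites(model)
        assert "B" in report.no_production and "B" in report.no_consumption

    def test_planted_orphan_found_exactly(self):
        model, truth = make_toy_model(ToyModelSpec(planted_gap=True))
        assert find_dead_end_metabolites(model).dead_end == truth.dead_end
        assert find_dead_end_metabolites(model, transitive=True).dead_end == truth.dead_end

    def test_transitive_propagation_through_closed_boundary(self):
        # closing the CO2 outlet orphans cytosolic CO2 only transitively
        model, _ = make_toy_model(ToyModelSpec())
        ex_co2 = model.reaction("EX_co2_e")
        ex_co2.lower_bound = ex_co2.upper_bound = 0.0
        root = find_dead_end_metabolites(model)
        assert "co2_e" in root.no_consumption and "co2_c" not in root.dead_end
        transitive = find_dead_end_metabolites(model, transitive=True)
        assert "co2_c" in transitive.no_consumption

    @pytest.mark.parametrize("seed", range(40))
    def test_transitive_scan_agrees_with_lp_oracle(self, seed):
        from gsmm import random_toy_spec

        model, _ = make_toy_model(random_toy_spec(seed))
        report = find_dead_end_metabolites(model, transitive=True)
        for met in model.metabolite_ids:
            assert (met in report.no_production) == (not lp_producible(model, met, "production")), met
            assert (met in report.no_consumption) == (not lp_producible(model, met, "consumption")), met


class TestSummary:
    def test_empty_model(self):
        summary = summarize_model(MetabolicModel(metabolites=[], reactions=[]))
        assert summary["genes"] == summary["reactions"] == summary["metabolites_total"] == 0

    def test_cell_model_counts(self, cell_model):
        summary = summarize_model(cell_model)
        assert summary["genes"] == len(cell_model.genes)
        assert summary["reactions"] == len(cell_model.reactions)
        assert summary["metabolites_total"] == len(cell_model.metabolites)
        # compartment-stripped species: each e/c pair collapses to one entry
        assert summary["metabolites_unique"] < summary["metabolites_total"]

    def test_compartment_classes_sum_to_total(self, cell_model, chain):
        for model in (cell_model, chain[0]):
            summary = summarize_model(model)
            assert sum(summary["reactions_by_compartment"].values()) == summary["reactions"]

    def test_transport_class_counts_cross_compartment_reactions(self, cell_model):
        summary = summarize_model(cell_model)
        transports = [
            r for r in cell_model.reactions
            if len({cell_model.metabolite(m).compartment for m in r.stoichiometry}) > 1
        ]
        assert summary["reactions_by_compartment"]["intercompartmental/transport"] == len(transports)
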