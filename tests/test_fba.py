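"""LP core and the growth/lipid simulation protocols."""

import numpy as np
import pytest

from oleaflux.biomass import compose_biomass, install_biomass
from oleaflux.fba import (
    ProtocolParams,
    carbon_atoms_of_exchange,
    fba,
    fix_exchange,
    growth_screen,
    knockout_growth,
    lipid_production_protocol,
    set_minimal_medium,
    uptake_for_equal_cmol,
)
from oleaflux.model import MetabolicModel, Metabolite, Reaction


def chain_model():
    """EX_A (lb -5) -> A_e -> A_c -> B_c -> B_e -> EX_B."""
    m = MetabolicModel("chain", compartments={"c": "c", "e": "e"})
    for mid, comp in [("a_e", "e"), ("a_c", "c"), ("b_c", "c"), ("b_e", "e")]:
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction(id="EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-5, upper_bound=1000))
    m.add_reaction(Reaction(id="At", stoichiometry={"a_e": -1, "a_c": 1}))
    m.add_reaction(Reaction(id="AB", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction(id="Bt", stoichiometry={"b_c": -1, "b_e": 1}))
    m.add_reaction(Reaction(id="EX_b_e", stoichiometry={"b_e": -1},
                            lower_bound=0, upper_bound=1000))
    return m


class TestFba:
    def test_chain_throughput_limited_by_uptake(self):
        sol = fba(chain_model(), "EX_b_e")
        assert sol.optimal and sol.objective == pytest.approx(5.0, abs=1e-9)

    def test_closed_exchanges_give_zero(self):
        m = chain_model()
        m.reactions["EX_a_e"].lower_bound = 0.0
        sol = fba(m, "EX_b_e")
        assert sol.optimal and sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_solution_satisfies_steady_state_and_bounds(self, toy_model):
        from oleaflux.model import stoichiometric_matrix

        sol = fba(toy_model, "BIOMASS")
        S, _, rxns = stoichiometric_matrix(toy_model)
        v = sol.fluxes[rxns].to_numpy()
        assert np.max(np.abs(S @ v)) <= 1e-6
        lb = np.array([toy_model.reactions[r].lower_bound for r in rxns])
        ub = np.array([toy_model.reactions[r].upper_bound for r in rxns])
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_infeasible_reported_not_raised(self):
        m = chain_model()
        m.reactions["AB"].lower_bound = 1.0  # forced flux, no supply
        m.reactions["EX_a_e"].lower_bound = 0.0
        m.reactions["EX_a_e"].upper_bound = 0.0
        m.reactions["EX_b_e"].upper_bound = 0.0
        sol = fba(m, "EX_b_e")
        assert sol.status == "infeasible" and sol.objective is None

    def test_agrees_with_cobra_glpk_oracle(self, toy_model, tmp_path):
        """Dual-solver check: the same LP via an independent formulation."""
        cobra = pytest.importorskip("cobra")
        from oleaflux.io import write_sbml

        p = tmp_path / "toy.xml"
        cases = []
        base = toy_model.copy()
        cases.append(base)
        alt = toy_model.copy()
        set_minimal_medium(alt, warn=False)
        fix_exchange(alt, "EX_glyc_e", 20.0)
        cases.append(alt)
        dyn = toy_model.copy()
        set_minimal_medium(dyn, warn=False)
        fix_exchange(dyn, "EX_glc_e", 5.0)
        fix_exchange(dyn, "EX_urea_e", 0.3)
        install_biomass(dyn, compose_biomass(40.0))
        cases.append(dyn)
        for model in cases:
            write_sbml(model, p)
            cm = cobra.io.read_sbml_model(str(p))
            reference = cm.optimize().objective_value
            ours = fba(model, "BIOMASS").objective
            assert ours == pytest.approx(reference, abs=1e-6)


class TestMinimalMedium:
    def test_carbon_closed_nutrients_open(self, toy_model):
        work = toy_model.copy()
        set_minimal_medium(work, warn=False)
        assert work.reactions["EX_glc_e"].lower_bound == 0.0
        assert work.reactions["EX_o2_e"].lower_bound == -1000.0
        assert work.reactions["EX_nh4_e"].lower_bound == -1000.0
        assert work.reactions["EX_lipid_e"].lower_bound == 0.0

    def test_no_carbon_no_growth(self, toy_model):
        work = toy_model.copy()
        set_minimal_medium(work, warn=False)
        sol = fba(work, "BIOMASS")
        mu = sol.objective if sol.optimal else 0.0
        assert mu <= 1e-6

    def test_missing_exchange_warned_not_fatal(self):
        m = chain_model()
        with pytest.warns(UserWarning, match="missing"):
            set_minimal_medium(m)


class TestEqualCmol:
    @pytest.mark.parametrize(
        "atoms,expected", [(3, 20.0), (12, 5.0), (6, 10.0), (5, 12.0)]
    )
    def test_uptake_scaling(self, atoms, expected):
        assert uptake_for_equal_cmol(atoms, 6, 10.0) == pytest.approx(expected)

    def test_zero_carbon_rejected(self):
        with pytest.raises(ValueError):
            uptake_for_equal_cmol(0, 6, 10.0)

    def test_atoms_read_from_exchange_species(self, toy_model):
        assert carbon_atoms_of_exchange(toy_model, "EX_sucr_e") == 12
        assert carbon_atoms_of_exchange(toy_model, "EX_glyc_e") == 3


class TestGrowthScreen:
    def test_ethanol_column_zero_glycerol_below_glucose(self, toy_model):
        table = growth_screen(
            toy_model,
            {"glucose": "EX_glc_e", "glycerol": "EX_glyc_e", "ethanol": "EX_etoh_e"},
            carbon_uptakes=[10.0, 20.0, 30.0],
            nitrogen_uptakes=[10.0],
        )
        # equal C-mol columns: glucose 10, glycerol 20, ethanol 30
        mu = lambda src, uc: table.query(
            "source == @src and carbon_uptake == @uc"
        ).mu.item()
        assert mu("ethanol", 30.0) <= 1e-6
        assert mu("glycerol", 20.0) < mu("glucose", 10.0)
        assert mu("glucose", 10.0) > 0.1

    def test_relaxing_both_uptakes_never_decreases_growth(self, toy_model):
        table = growth_screen(
            toy_model, {"glucose": "EX_glc_e"},
            carbon_uptakes=[5.0, 10.0], nitrogen_uptakes=[2.0, 4.0],
        )
        lo = table.query("carbon_uptake == 5.0 and nitrogen_uptake == 2.0").mu.item()
        hi = table.query("carbon_uptake == 10.0 and nitrogen_uptake == 4.0").mu.item()
        assert hi >= lo - 1e-9


class TestLipidProtocol:
    def test_biomass_window_caps_at_mu_max(self, toy_model):
        res = lipid_production_protocol(
            toy_model, 40.0, "EX_glc_e", 10.0, "EX_urea_e", 0.5
        )
        assert res.mu_star > 0.2
        assert res.mu_bounds == (pytest.approx(0.18), pytest.approx(0.20))
        assert res.lipid_flux > 0

    def test_window_tracks_low_growth(self, toy_model):
        res = lipid_production_protocol(
            toy_model, 13.0, "EX_glc_e", 1.5, "EX_urea_e", 0.3
        )
        assert 0 < res.mu_star < 0.2
        assert res.mu_bounds == (
            pytest.approx(0.9 * res.mu_star), pytest.approx(res.mu_star)
        )

    def test_closing_lipid_exchange_zeroes_flux(self, toy_model):
        work = toy_model.copy()
        work.reactions["EX_lipid_e"].upper_bound = 0.0
        res = lipid_production_protocol(
            work, 40.0, "EX_glc_e", 10.0, "EX_urea_e", 0.5
        )
        assert res.lipid_flux == pytest.approx(0.0, abs=1e-9)

    def test_biomass_coupled_lipid_rises_with_cn_at_fixed_carbon(self, toy_model):
        """Condition-specific biomass drives lipid accumulation with C/N."""
        rates = {}
        for cn in (6.0, 120.0):
            res = lipid_production_protocol(
                toy_model, cn, "EX_glc_e", 4.0, "EX_urea_e",
                nitrogen_uptake=4.0 * 6 * 12.011 / (cn * 14.007) / 2,
            )
            mu_used = res.solution.fluxes["BIOMASS"]
            rates[cn] = mu_used * compose_biomass(cn).w_lipid
        assert rates[6.0] < 0.2 * rates[120.0]

    def test_no_growth_flagged_when_window_infeasible(self, toy_model):
        res = lipid_production_protocol(
            toy_model, 40.0, "EX_etoh_e", 30.0, "EX_urea_e", 0.5
        )
        assert res.no_growth and res.lipid_flux == 0.0


class TestKnockout:
    _cond = dict(cn_gg=40.0, carbon_exchange="EX_glc_e", carbon_uptake=10.0,
                 nitrogen_exchange="EX_urea_e", nitrogen_uptake=0.5)

    def test_empty_deletion_matches_wild_type(self, toy_model):
        wt = lipid_production_protocol(toy_model, **self._cond)
        ko = knockout_growth(toy_model, [], **self._cond)
        assert ko.mu_star == pytest.approx(wt.mu_star, abs=1e-9)

    def test_acl_deletion_abolishes_growth_and_lipid(self, toy_model, toy_manifest):
        ko = knockout_growth(toy_model, [toy_manifest.acl_gene], **self._cond)
        assert ko.mu_star <= 1e-6 and ko.lipid_flux == 0.0

    def test_redundant_isozyme_deletion_neutral(self, toy_model):
        # HXK1/HXK2 are an OR pair: deleting one leaves hexokinase active
        wt = lipid_production_protocol(toy_model, **self._cond)
        ko = knockout_growth(toy_model, ["gHXK1"], **self._cond)
        assert ko.mu_star == pytest.approx(wt.mu_star, abs=1e-6)

    def test_unknown_gene_rejected(self, toy_model):
        with pytest.raises(KeyError):
            knockout_growth(toy_model, ["gNOPE"], **self._cond)
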