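"""Condition-specific biomass: C/N arithmetic, quadratic lipid model,
macromolecule partitioning, acyl-CoA pool and reaction assembly."""

import math

import numpy as np
import pytest

from oleaflux.biomass import (
    ACYL_POOL_COEFFICIENTS,
    BIOMASS_COMPONENT_IDS,
    CompositionError,
    LIPID_CN_VERTEX,
    MediumComponent,
    MediumSpec,
    acyl_pool_fractions,
    acyl_pool_reaction,
    assemble_biomass_reaction,
    biomass_molecular_weight,
    cn_molar_to_mass,
    cn_ratio_from_medium,
    compose_biomass,
    composition_from_reaction,
    lipid_weight_percent,
)


def medium(glycerol_g, nh4cl_g):
    return MediumSpec(
        components=[
            MediumComponent("glycerol", "C3H8O3", concentration_g_l=glycerol_g,
                            role="carbon"),
            MediumComponent("nh4cl", "NH4Cl", concentration_g_l=nh4cl_g,
                            role="nitrogen"),
        ]
    )


class TestCNRatio:
    def test_medium_a_is_cn_28(self):
        # 16 g/l glycerol + 1 g/l NH4Cl
        ratio = cn_ratio_from_medium(medium(16.0, 1.0))
        assert ratio.molar == pytest.approx(27.9, abs=0.05)
        assert round(ratio.molar) == 28

    def test_medium_b_is_cn_2_8(self):
        # 8 g/l glycerol + 5 g/l NH4Cl
        ratio = cn_ratio_from_medium(medium(8.0, 5.0))
        assert ratio.molar == pytest.approx(2.79, abs=0.01)

    def test_equal_molar_carbon_and_nitrogen_gives_one(self):
        m = MediumSpec(
            components=[
                MediumComponent("c1", "C", uptake_mmol=3.0),
                MediumComponent("n1", "N", uptake_mmol=3.0),
            ]
        )
        assert cn_ratio_from_medium(m).molar == pytest.approx(1.0)

    def test_scaling_invariance(self):
        a = cn_ratio_from_medium(medium(16.0, 1.0))
        b = cn_ratio_from_medium(medium(16.0 * 7.3, 1.0 * 7.3))
        assert a.molar == pytest.approx(b.molar, rel=1e-12)

    def test_nitrogen_free_medium_is_infinite(self):
        m = MediumSpec(components=[MediumComponent("g", "C3H8O3", uptake_mmol=1.0)])
        assert math.isinf(cn_ratio_from_medium(m).molar)

    @pytest.mark.parametrize(
        "molar,mass", [(12.83, 11.0), (0.0, 0.0), (28.0, 24.01)]
    )
    def test_molar_to_mass_conversion(self, molar, mass):
        assert cn_molar_to_mass(molar) == pytest.approx(mass, abs=0.005)

    def test_negative_molar_rejected(self):
        with pytest.raises(ValueError):
            cn_molar_to_mass(-1.0)


class TestLipidContent:
    @pytest.mark.parametrize(
        "cn,expected", [(0.0, 1.9), (100.0, 40.9), (147.5, 45.4125)]
    )
    def test_quadratic_values(self, cn, expected):
        assert lipid_weight_percent(cn) == pytest.approx(expected, abs=1e-9)

    def test_vertex_is_global_maximum(self):
        xs = np.linspace(0, 300, 3001)
        ys = [lipid_weight_percent(x) for x in xs]
        assert max(ys) == pytest.approx(lipid_weight_percent(LIPID_CN_VERTEX))
        assert LIPID_CN_VERTEX == pytest.approx(147.5)

    def test_monotone_up_to_vertex(self):
        xs = np.linspace(0, 147.5, 500)
        ys = [lipid_weight_percent(x) for x in xs]
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))

    def test_decreases_beyond_vertex_no_plateau(self):
        assert lipid_weight_percent(240) < lipid_weight_percent(147.5)

    def test_floor_at_zero(self):
        # far beyond the vertex the fitted polynomial goes negative; clamp
        assert lipid_weight_percent(500) == 0.0


class TestComposition:
    def test_partition_at_cn_100(self):
        c = compose_biomass(100.0)
        assert c.w_carbohydrate == pytest.approx(0.11)
        assert c.w_lipid == pytest.approx(0.409)
        assert c.w_protein == pytest.approx(0.431)
        assert c.w_other == pytest.approx(0.05)

    def test_partition_at_cn_0(self):
        c = compose_biomass(0.0)
        assert c.w_lipid == pytest.approx(0.019)
        assert c.w_protein == pytest.approx(0.821)

    @pytest.mark.parametrize("cn", [0, 6, 28, 60, 120, 147.5, 240])
    def test_fractions_sum_to_one(self, cn):
        c = compose_biomass(cn)
        total = c.w_carbohydrate + c.w_protein + c.w_lipid + c.w_other
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_carbohydrate_constant_across_cn(self):
        values = {compose_biomass(cn).w_carbohydrate for cn in (6, 60, 120)}
        assert values == {0.11}

    def test_replete_mode_static(self):
        a, b = compose_biomass(6, "replete"), compose_biomass(240, "replete")
        assert (a.w_carbohydrate, a.w_protein, a.w_lipid) == (
            b.w_carbohydrate, b.w_protein, b.w_lipid
        )


class TestAcylPool:
    def test_printed_coefficients_sum(self):
        assert sum(ACYL_POOL_COEFFICIENTS.values()) == pytest.approx(0.966525)

    def test_normalized_fractions_match_reported_shares(self):
        frac = acyl_pool_fractions()
        assert frac["C18:1"] == pytest.approx(0.55233 / 0.966525)
        assert round(frac["C18:1"] * 100) == 57
        # the stated weight percentages sum to 99, the pool coefficients to
        # 0.9665; normalization reconciles them to within one point
        assert frac["C16:0"] * 100 == pytest.approx(25.0, abs=1.0)
        assert frac["C18:0"] * 100 == pytest.approx(10.0, abs=1.0)
        assert frac["C18:2"] * 100 == pytest.approx(7.0, abs=1.0)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_reaction_uses_exact_coefficients(self):
        rxn = acyl_pool_reaction()
        assert rxn.stoichiometry["odecoa_c"] == -0.55233
        assert rxn.stoichiometry["pmtcoa_c"] == -0.24952
        assert rxn.stoichiometry["stcoa_c"] == -0.096712
        assert rxn.stoichiometry["lnlccoa_c"] == -0.067963
        assert rxn.stoichiometry["acylcoa_pool_c"] == 1.0
        assert rxn.pseudo


class TestAssembly:
    @pytest.mark.parametrize("cn", [0, 6, 60, 240])
    def test_biomass_mw_is_one_g_per_mmol(self, toy_model, cn):
        rxn = assemble_biomass_reaction(compose_biomass(cn), toy_model)
        assert biomass_molecular_weight(rxn, toy_model) == pytest.approx(1.0, abs=1e-6)

    def test_tag_mass_share_is_90_percent_of_lipid(self, toy_model):
        comp = compose_biomass(100.0)
        rxn = assemble_biomass_reaction(comp, toy_model)
        masses = composition_from_reaction(rxn, toy_model)
        lipid = masses["tag"] + masses["ps"] + masses["pe"] + masses["pc"]
        assert masses["tag"] == pytest.approx(comp.w_lipid * 0.90, abs=1e-12)
        assert masses["tag"] / lipid == pytest.approx(0.90, abs=1e-12)

    def test_round_trip_recovers_fractions(self, toy_model):
        for cn in (0, 28, 120):
            comp = compose_biomass(cn)
            masses = composition_from_reaction(
                assemble_biomass_reaction(comp, toy_model), toy_model
            )
            assert masses["carbohydrate"] == pytest.approx(comp.w_carbohydrate, abs=1e-9)
            assert masses["protein"] == pytest.approx(comp.w_protein, abs=1e-9)
            lipid = masses["tag"] + masses["ps"] + masses["pe"] + masses["pc"]
            assert lipid == pytest.approx(comp.w_lipid, abs=1e-9)
            assert masses["other"] == pytest.approx(comp.w_other, abs=1e-9)

    def test_deterministic(self, toy_model):
        a = assemble_biomass_reaction(compose_biomass(42.0), toy_model)
        b = assemble_biomass_reaction(compose_biomass(42.0), toy_model)
        assert a.stoichiometry == b.stoichiometry

    def test_substrate_coefficients_negative(self, toy_model):
        rxn = assemble_biomass_reaction(compose_biomass(60.0), toy_model)
        for mid in BIOMASS_COMPONENT_IDS.values():
            if mid in rxn.stoichiometry:
                assert rxn.stoichiometry[mid] < 0

    def test_missing_pseudo_species_named_in_error(self):
        from oleaflux.model import MetabolicModel

        empty = MetabolicModel("x", compartments={"c": "c"})
        with pytest.raises(CompositionError, match="carbohydrate_c"):
            assemble_biomass_reaction(compose_biomass(10.0), empty)
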