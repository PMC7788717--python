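"""Scenario runners: grids, carbon-source screens, sampled C/N series."""

import numpy as np
import pandas as pd
import pytest

from oleaflux.scenarios import (
    RunManifest,
    scenario_acetylcoa,
    scenario_carbon_sources,
    scenario_cn_grid,
    scenario_zscore_series,
)


@pytest.fixture(scope="module")
def grid(toy_model):
    return scenario_cn_grid(
        toy_model,
        carbon_uptakes=[1.5, 3.0, 5.0, 8.5],
        nitrogen_uptakes=[0.3],
    )


@pytest.fixture(scope="module")
def source_table(toy_model, toy_manifest):
    return scenario_carbon_sources(toy_model, toy_manifest, nitrogen_uptakes=[10.0])


@pytest.fixture(scope="module")
def acoa_series(toy_model, toy_manifest):
    return scenario_acetylcoa(
        toy_model, toy_manifest, cn_list=[6, 10, 24, 60], n=150, seed=9
    )


@pytest.fixture(scope="module")
def z_series(toy_model, toy_manifest):
    return scenario_zscore_series(
        toy_model, toy_manifest, cn_list=[6, 12, 60],
        carbon_levels=[16.0], n=150, seed=13,
    )


class TestCnGrid:
    def test_dynamic_lipid_accumulation_rises_with_cn(self, grid):
        dyn = grid.query("mode == 'dynamic'").sort_values("cn_gg")
        assert dyn.biomass_lipid_rate.is_monotonic_increasing
        assert dyn.lipid_exchange.is_monotonic_increasing

    def test_static_lipid_accumulation_flat_once_growth_caps(self, grid):
        capped = grid.query("mode == 'static' and mu_star > 0.2")
        assert len(capped) >= 2
        assert capped.biomass_lipid_rate.std() <= 1e-9

    def test_single_cell_matches_direct_protocol_call(self, toy_model):
        from oleaflux.fba import lipid_production_protocol

        cell = scenario_cn_grid(
            toy_model, carbon_uptakes=[4.0], nitrogen_uptakes=[0.3],
            modes=("dynamic",),
        ).iloc[0]
        direct = lipid_production_protocol(
            toy_model, cell.cn_gg, "EX_glc_e", 4.0, "EX_urea_e", 0.3
        )
        assert cell.lipid_exchange == pytest.approx(direct.lipid_flux, abs=1e-9)
        assert cell.mu_star == pytest.approx(direct.mu_star, abs=1e-9)

    def test_monotone_along_carbon_axis_before_vertex(self, grid):
        dyn = grid.query("mode == 'dynamic'").sort_values("carbon_uptake")
        before_vertex = dyn[dyn.cn_gg <= 147.5]
        assert before_vertex.total_lipid_rate.is_monotonic_increasing


class TestCarbonSources:
    def test_ethanol_row_all_zero(self, source_table):
        etoh = source_table.query("source == 'ethanol'")
        assert (etoh.mu_star <= 1e-6).all()
        assert (etoh.lipid_exchange == 0).all()

    def test_sugars_comparable_glycerol_lower(self, source_table):
        mu = source_table.set_index("source").mu_star
        sugars = [mu["glucose"], mu["fructose"], mu["sucrose"], mu["xylose"]]
        assert min(sugars) > 0.85 * max(sugars)
        assert mu["glycerol"] < mu["glucose"]

    def test_equal_cmol_normalization_applied(self, source_table):
        uptake = source_table.set_index("source").carbon_uptake
        assert uptake["glycerol"] == pytest.approx(2 * uptake["glucose"])
        assert uptake["sucrose"] == pytest.approx(uptake["glucose"] / 2)


class TestAcetylCoaSeries:
    def test_tracked_fluxes_rise_past_cn_10(self, acoa_series):
        for label in ("acl", "citrate_transport", "acyl_pool", "lipid_exchange"):
            means = acoa_series[acoa_series.reaction == label].set_index("cn_gg")["mean"]
            assert means[60] > means[24] > means[10], label
            assert means[60] > 2 * means[10], label

    def test_citrate_export_moves_with_acl(self, acoa_series):
        acl = acoa_series[acoa_series.reaction == "acl"].set_index("cn_gg")["mean"]
        cit = acoa_series[acoa_series.reaction == "citrate_transport"].set_index("cn_gg")["mean"]
        assert np.corrcoef(acl, cit)[0, 1] > 0.99

    def test_acl_knockout_zeroes_lipid_series(self, toy_model, toy_manifest):
        ko = scenario_acetylcoa(
            toy_model, toy_manifest, cn_list=[24], n=50, seed=9,
            knockout_genes=[toy_manifest.acl_gene],
        )
        lipid = ko[ko.reaction == "lipid_exchange"]
        assert (lipid["mean"] == 0).all() and (~lipid.feasible).all()

    def test_reports_sd_and_se(self, acoa_series):
        ok = acoa_series[acoa_series.feasible]
        assert (ok.sd >= 0).all()
        assert np.allclose(ok.se, ok.sd / np.sqrt(150))


class TestZScoreSeries:
    def test_one_zscore_table_per_non_reference_condition(self, z_series):
        with_z = [r for r in z_series if r.zscores is not None]
        refs = [r for r in z_series if r.cn_gg == 6.0]
        assert len(with_z) == 2 and len(refs) == 1
        assert refs[0].zscores is None

    def test_tca_and_ppp_shifts_positive_at_high_cn(self, z_series, toy_manifest):
        high = next(r for r in z_series if r.cn_gg == 60.0)
        z = high.zscores["z"]
        tca = z[toy_manifest.pathways["TCA"]]
        ppp = z[toy_manifest.pathways["pentose phosphate pathway"]]
        assert (tca > 0).mean() > 0.5
        assert (ppp > 0).mean() > 0.5

    def test_seeded_run_reproducible(self, toy_model, toy_manifest, z_series):
        again = scenario_zscore_series(
            toy_model, toy_manifest, cn_list=[6, 12, 60],
            carbon_levels=[16.0], n=150, seed=13,
        )
        a = next(r for r in z_series if r.cn_gg == 60.0)
        b = next(r for r in again if r.cn_gg == 60.0)
        pd.testing.assert_frame_equal(a.sampling.points, b.sampling.points)


class TestRunManifest:
    def test_fingerprint_stable_and_sensitive(self, toy_model):
        a = RunManifest.fingerprint(toy_model)
        assert a == RunManifest.fingerprint(toy_model)
        mutated = toy_model.copy()
        mutated.reactions["ACL"].upper_bound = 999.0
        assert RunManifest.fingerprint(mutated) != a
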