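"""Synthetic LTE panels, toy crop surface, thermal time, weather generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import yieldstab as ys
from yieldstab.errors import DomainError, YieldStabError


def _config(**overrides) -> ys.SyntheticPanelConfig:
    base = dict(n_treatments=3, n_environments=8, base_means=(1.0, 2.0, 3.0),
                fw_slopes=(0.8, 1.0, 1.2), env_mean=2.0, env_sd=0.3, seed=0)
    base.update(overrides)
    return ys.SyntheticPanelConfig(**base)


class TestPanelGenerator:
    def test_zero_noise_unit_slope_equals_environment_index(self):
        cfg = _config(fw_slopes=(1.0, 1.0, 1.0), base_means=(2.0, 2.0, 2.0),
                      taylor_c=0.0)
        mat = ys.pivot_matrix(ys.generate_lte_panel(cfg), "observed")
        # beta_i = 0 and alpha_i = 1, so every treatment IS omega_j
        assert np.allclose(mat.to_numpy(), mat.to_numpy()[0], atol=1e-12)

    def test_same_seed_reproduces_panel(self):
        a = ys.generate_lte_panel(_config(seed=9)).data
        b = ys.generate_lte_panel(_config(seed=9)).data
        pd.testing.assert_frame_equal(a, b)
        c = ys.generate_lte_panel(_config(seed=10)).data
        assert not np.allclose(a["grain_yield"], c["grain_yield"])

    @pytest.mark.parametrize("b_star", [1.0, 1.5, 2.0])
    def test_taylor_exponent_recovered(self, b_star):
        cfg = _config(n_treatments=6, n_environments=200,
                      base_means=(0.5, 1.0, 2.0, 3.0, 4.5, 6.0),
                      fw_slopes=(1.0,) * 6, env_mean=3.0, env_sd=0.01,
                      taylor_b=b_star, taylor_c=0.02, seed=int(10 * b_star))
        mat = ys.pivot_matrix(ys.generate_lte_panel(cfg), "observed")
        fit = ys.fit_taylor(ys.summarize(mat))
        assert fit.b == pytest.approx(b_star, abs=0.1)

    def test_strict_mode_rejects_heavy_truncation(self):
        cfg = _config(base_means=(0.1, 0.1, 0.1), taylor_b=0.0, taylor_c=0.25, seed=2)
        with pytest.raises(YieldStabError):
            ys.generate_lte_panel(cfg, strict=True)


class TestPresets:
    @pytest.mark.parametrize("name, n_treatments", [("sadore_millet", 12), ("ndiaye_rice", 8)])
    def test_preset_structure(self, name, n_treatments):
        cfg = ys.preset_panel_config(name)
        assert cfg.n_treatments == n_treatments
        assert cfg.n_environments == 8
        panel = ys.generate_lte_panel(cfg)
        assert len(panel) == 2 * n_treatments * 8
        if name == "ndiaye_rice":
            assert set(panel.data["season"]) == {"HDS", "WS"}

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            ys.preset_panel_config("nowhere")

    @pytest.mark.parametrize("name", ["sadore_millet", "ndiaye_rice"])
    def test_generated_means_match_targets_over_seeds(self, name):
        """Across 50 seeds, per-treatment grand means sit on the analytic
        truncated-normal targets (marginally each yield is Gaussian around
        the treatment mean, truncated at zero)."""
        cfg0 = ys.preset_panel_config(name)
        base = np.asarray(cfg0.base_means)
        tot_sd = np.sqrt(np.asarray(cfg0.fw_slopes) ** 2 * cfg0.env_sd ** 2
                         + cfg0.noise_sd ** 2)
        z = base / tot_sd
        target = base * norm.cdf(z) + tot_sd * norm.pdf(z)
        per_seed = []
        for seed in range(50):
            panel = ys.generate_lte_panel(ys.preset_panel_config(name, seed=seed))
            mat = ys.pivot_matrix(panel, "observed").reindex(list(cfg0.treatment_ids))
            per_seed.append(mat.mean(axis=1).to_numpy())
        per_seed = np.array(per_seed)
        se = per_seed.std(axis=0, ddof=1) / np.sqrt(50)
        zscores = (per_seed.mean(axis=0) - target) / se
        # panel-level summary within 2 SE; per-treatment at a
        # multiplicity-aware bound (max of ~12 standard normals)
        assert abs(zscores.mean()) < 2.0
        assert np.abs(zscores).max() < 3.5

    def test_shrunk_predictions_are_more_stable(self):
        """Predicted series generated with shrinkage < 1 show lower mean
        adjusted CV than observations in nearly every replicate."""
        wins = 0
        for seed in range(50):
            panel = ys.generate_lte_panel(ys.preset_panel_config("ndiaye_rice", seed=seed))
            table = ys.stability_table(panel)
            acv = table.pivot_table(index="treatment_id", columns="source", values="acv")
            wins += acv["predicted"].mean() < acv["observed"].mean()
        assert wins >= 45

    def test_noise_free_identity_round_trip_gives_unit_concordance(self):
        """With shrinkage 1, no bias and vanishing noise the observed- and
        predicted-based stability measures agree perfectly (CCC -> 1)."""
        cfg = _config(n_treatments=4, base_means=(1.0, 2.0, 3.0, 4.0),
                      fw_slopes=(0.7, 0.9, 1.1, 1.3), taylor_c=1e-8,
                      prediction_shrinkage=1.0, prediction_bias=0.0, seed=6)
        table = ys.stability_table(ys.generate_lte_panel(cfg))
        obs = table[table["source"] == "observed"][["treatment_id", "acv", "syi", "fw_slope"]]
        pred = table[table["source"] == "predicted"][["treatment_id", "acv", "syi", "fw_slope"]]
        agreement = ys.stability_agreement(obs, pred)
        assert (agreement["ccc"] > 0.99).all()


class TestToyCropModel:
    def test_deterministic_per_context(self):
        point = {"tt_juvenile": 300.0, "tt_grainfill": 500.0, "rue": 1.6, "grain_wt": 25.0}
        a = ys.toy_crop_model(point, "2015")
        b = ys.toy_crop_model(point, "2015")
        c = ys.toy_crop_model(point, "2016")
        assert a == b
        assert a != c
        assert set(a) == {"yield", "biomass"}

    def test_failure_region_returns_missing(self):
        point = {"tt_juvenile": 490.0, "tt_grainfill": 790.0, "rue": 1.6, "grain_wt": 25.0}
        assert ys.toy_crop_model(point, "y") is None

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            ys.toy_crop_model({"tt_juvenile": 50.0, "tt_grainfill": 500.0,
                               "rue": 1.6, "grain_wt": 25.0}, "y")

    def test_designed_interaction_detectable(self):
        res = ys.saltelli_indices(ys.toy_crop_model, ys.TOY_CROP_SPECS,
                                  n_base=4096, seed=31)
        got = res.indices[res.indices["output"] == "yield"].set_index("parameter")
        assert got.loc["tt_grainfill", "st"] - got.loc["tt_grainfill", "s"] > 0.05


class TestThermalTime:
    def test_reference_values(self):
        p = ys.ThermalTimeParams()
        assert ys.thermal_time(25.0, p) == pytest.approx(10.0)
        assert ys.thermal_time(15.0, p) == 0.0
        assert ys.thermal_time(40.0, p) == pytest.approx(19.0)  # plateau at tod - tbd
        zero_mode = ys.ThermalTimeParams(above_optimum="zero")
        assert ys.thermal_time(40.0, zero_mode) == 0.0

    @given(st.floats(-20.0, 34.0), st.floats(0.0, 10.0))
    def test_nondecreasing_below_optimum(self, t, dt):
        p = ys.ThermalTimeParams()
        hi = min(t + dt, p.tod)
        assert ys.thermal_time(hi, p) >= ys.thermal_time(t, p)

    def test_accumulator_over_weather_series(self):
        weather = pd.DataFrame({"tmin": [10.0, 20.0, 30.0], "tmax": [20.0, 30.0, 44.0]})
        gdd = ys.cumulative_thermal_time(weather)
        # daily means 15, 25, 37 -> increments 0, 10, 19 (capped)
        assert gdd.to_list() == pytest.approx([0.0, 10.0, 29.0])


class TestWeatherGenerator:
    def test_sadore_annual_rainfall_envelope(self):
        weather = ys.generate_weather("sadore", n_years=40, seed=12)
        annual = weather.groupby(weather["date"].dt.year)["rain"].sum()
        assert 480 <= annual.mean() <= 650

    def test_physical_invariants_and_determinism(self):
        a = ys.generate_weather("ndiaye", n_years=2, seed=3)
        b = ys.generate_weather("ndiaye", n_years=2, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert (a["tmin"] <= a["tmax"]).all()
        assert (a["rain"] >= 0).all()
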