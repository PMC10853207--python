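"""Generators: determinism, zero-noise identity, construction properties."""

import numpy as np
import pandas as pd
import pytest

from soilprime.calibrate import FieldSetup, field_observables
from soilprime.mend import MendParams
from soilprime.synth import (SynthConfig, make_field_dataset,
                             make_lab_incubation, make_pls_dataset,
                             make_qsip_dataset, synthetic_forcing)


class TestLabIncubation:
    def test_zero_noise_equals_truth(self):
        cfg = SynthConfig(seed=3, respiration_noise_cv=0.0)
        series, truth = make_lab_incubation(cfg)
        merged = series.merge(truth["series"],
                              on=["treatment", "straw_group", "replicate",
                                  "day"], suffixes=("", "_t"))
        assert np.array_equal(merged.total_ugC_g, merged.total_ugC_g_t)
        assert np.array_equal(merged.c13_ugC_g, merged.c13_ugC_g_t)

    def test_seeded_determinism(self):
        a, _ = make_lab_incubation(SynthConfig(seed=8))
        b, _ = make_lab_incubation(SynthConfig(seed=8))
        pd.testing.assert_frame_equal(a, b)

    def test_c13_bounded_by_total_every_day(self):
        series, _ = make_lab_incubation(SynthConfig(seed=4,
                                                    respiration_noise_cv=0.2))
        assert (series.c13_ugC_g <= series.total_ugC_g + 1e-12).all()

    def test_bad_parameters_raise_with_diagnostic(self):
        cfg = SynthConfig(seed=0)
        cfg.true_params = MendParams(y_g=1.5)
        with pytest.raises(Exception):
            make_lab_incubation(cfg)


class TestQsipGenerator:
    def test_determinism(self):
        a, _ = make_qsip_dataset(SynthConfig(seed=2, n_asvs=15, n_active=3))
        b, _ = make_qsip_dataset(SynthConfig(seed=2, n_asvs=15, n_active=3))
        pd.testing.assert_frame_equal(a.fractions, b.fractions)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_nonpositive_shift_rejected(self):
        cfg = SynthConfig(seed=0, n_asvs=10, n_active=2)
        cfg.density_shift_mean = 0.0
        with pytest.raises(ValueError):
            make_qsip_dataset(cfg)

    def test_too_many_active_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(seed=0, n_asvs=5, n_active=6)

    def test_density_grid_spans_gradient(self):
        ds, _ = make_qsip_dataset(SynthConfig(seed=1, n_asvs=10, n_active=2))
        assert ds.fractions.density_g_ml.min() == pytest.approx(1.66)
        assert ds.fractions.density_g_ml.max() == pytest.approx(1.77)


class TestFieldGenerator:
    @pytest.fixture(scope="class")
    def small_field(cls):
        cfg = SynthConfig(seed=6, field_years=1)
        return cfg, make_field_dataset(cfg, spin_up_years=10.0, step_h=12.0)

    def test_zero_noise_equals_simulation(self):
        cfg = SynthConfig(seed=6, field_years=1,
                          observation_noise={k: 0.0 for k in
                                             ("rh", "mbc", "active_fraction",
                                              "enz_o", "enz_h")})
        setup, obs, truth = make_field_dataset(cfg, spin_up_years=10.0,
                                               step_h=12.0,
                                               gene_scales=(1.0, 1.0))
        sim = field_observables(cfg.true_params, setup)
        for var in obs:
            assert np.allclose(obs[var], sim[var], rtol=1e-12), var

    def test_gene_abundance_proportional_to_enzymes(self, small_field):
        cfg, (setup, obs, truth) = small_field
        clean = truth["observables"]
        r = np.corrcoef(clean["enz_o"],
                        clean["enz_o"] * truth["gene_scales"][0])[0, 1]
        assert r == pytest.approx(1.0)

    def test_warming_raises_cumulative_rh(self):
        cfg = SynthConfig(seed=6, field_years=1)
        base = synthetic_forcing(cfg)
        warm = synthetic_forcing(cfg, warming_offset_c=3.0)
        # same weather noise, shifted temperature
        assert np.allclose(warm.temp_c - base.temp_c, 3.0)
        p = cfg.true_params
        from soilprime.mend import default_lab_state, simulate_mend
        s = default_lab_state()
        rh_b = simulate_mend(s, p, base, step_h=12.0,
                             output_every_h=24.0)["co2_cum"][-1]
        rh_w = simulate_mend(s, p, warm, step_h=12.0,
                             output_every_h=24.0)["co2_cum"][-1]
        assert rh_w >= rh_b  # Q10 > 1

    def test_observation_shapes_consistent(self, small_field):
        cfg, (setup, obs, truth) = small_field
        assert len(obs["rh"]) == setup.n_days
        n_sparse = len(setup.sparse_days())
        for var in ("mbc", "active_fraction", "enz_o", "enz_h"):
            assert len(obs[var]) == n_sparse


class TestPlsGenerator:
    def test_zero_noise_single_factor_fully_explained(self):
        from soilprime.plsstats import pls_fit
        cfg = SynthConfig(seed=12)
        x, y, mask = make_pls_dataset(cfg, n_samples=30, n_predictors=4,
                                      n_loading=4, noise_sd=0.0)
        res = pls_fit(x.to_numpy(), y, n_components=1)
        assert res.r2y == pytest.approx(1.0, abs=1e-9)

    def test_null_predictors_average_vip_below_one(self):
        from soilprime.plsstats import pls_fit
        vips = []
        for seed in range(100):
            x, y, mask = make_pls_dataset(SynthConfig(seed=seed),
                                          n_samples=30, n_predictors=6,
                                          n_loading=2, noise_sd=0.3)
            res = pls_fit(x.to_numpy(), y, n_components=1)
            vips.append(res.vip()[~mask].mean())
        assert np.mean(vips) < 1.0

    def test_determinism(self):
        a = make_pls_dataset(SynthConfig(seed=3))
        b = make_pls_dataset(SynthConfig(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_minimum_predictors_enforced(self):
        with pytest.raises(ValueError):
            make_pls_dataset(SynthConfig(seed=0), n_predictors=1)
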