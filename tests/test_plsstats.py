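"""Response ratio, PCoA round trips and the PLS partial-R2 machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression

from soilprime.plsstats import (bray_curtis, forward_select_pls, pcoa_axes,
                                pls_fit, pls_permutation_test,
                                response_ratio_test)
from soilprime.synth import SynthConfig, make_pls_dataset


class TestResponseRatio:
    def test_equal_means_not_significant(self):
        res = response_ratio_test(2.0, 0.3, 4, 2.0, 0.3, 4)
        assert res.rr == 0.0
        assert not res.significant

    def test_hand_computed_interval(self):
        # RR = ln 2; SE = sqrt(0.04/(4*4) + 0.01/(4*1)) = 0.0707
        res = response_ratio_test(2.0, 0.2, 4, 1.0, 0.1, 4)
        assert res.rr == pytest.approx(np.log(2), rel=1e-9)
        assert res.se == pytest.approx(0.07071, rel=1e-3)
        assert res.ci_low == pytest.approx(0.5545, rel=1e-3)
        assert res.ci_high == pytest.approx(0.8318, rel=1e-3)
        assert res.significant

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        n_rej = 0
        reps = 1000
        for _ in range(reps):
            a = rng.lognormal(0.0, 0.2, 6)
            b = rng.lognormal(0.0, 0.2, 6)
            res = response_ratio_test(a.mean(), a.std(ddof=1), 6,
                                      b.mean(), b.std(ddof=1), 6)
            n_rej += res.significant
        # z-test with estimated SDs at n=6 is mildly anticonservative
        assert 0.02 <= n_rej / reps <= 0.12

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (4, 16, 64):
            res = response_ratio_test(2.0, 0.4, n, 1.5, 0.4, n)
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] == pytest.approx(widths[0] / 2, rel=1e-6)
        assert widths[2] == pytest.approx(widths[1] / 2, rel=1e-6)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            response_ratio_test(0.0, 0.1, 4, 1.0, 0.1, 4)


class TestPcoa:
    def test_identical_samples_identical_coordinates(self):
        counts = np.array([[5, 5, 0], [5, 5, 0], [0, 0, 10]], float)
        dm = bray_curtis(counts)
        assert dm[0, 1] == 0.0
        coords = pcoa_axes(dm, k=1)
        assert np.allclose(coords[0], coords[1], atol=1e-12)

    def test_disjoint_taxa_distance_one(self):
        counts = np.array([[4, 4, 0, 0], [0, 0, 3, 3]], float)
        assert bray_curtis(counts)[0, 1] == pytest.approx(1.0)

    def test_euclidean_round_trip(self):
        # 4 points in the plane: recovered coordinates reproduce distances
        pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1]], float)
        dm = squareform(pdist(pts))
        coords = pcoa_axes(dm, k=2)
        dm2 = squareform(pdist(coords))
        assert np.allclose(dm, dm2, atol=1e-8)

    def test_too_many_axes_warns_and_truncates(self):
        pts = np.array([[0.0], [1.0], [2.5]])
        dm = squareform(pdist(pts))
        with pytest.warns(UserWarning):
            coords = pcoa_axes(dm, k=5)
        assert coords.shape[1] < 5


class TestPlsFit:
    def test_univariate_perfect_relationship(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        res = pls_fit(x, 3.0 * x.ravel() - 1.0, n_components=1)
        assert res.r2y == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_unexplained(self):
        # y orthogonal to a single centred predictor: R2Y ~ 0
        x = np.array([-1.0, 1.0, -1.0, 1.0]).reshape(-1, 1)
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        res = pls_fit(x, y, n_components=1)
        assert res.r2y == pytest.approx(0.0, abs=1e-12)

    def test_one_component_matches_simple_regression(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 1))
        y = 2.0 * x.ravel() + rng.normal(0, 0.5, 30)
        res = pls_fit(x, y, n_components=1)
        r = np.corrcoef(x.ravel(), y)[0, 1]
        assert res.r2y == pytest.approx(r ** 2, rel=1e-9)

    def test_matches_sklearn_prediction(self):
        """Independent cross-check of the NIPALS fit against sklearn."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 6))
        y = x[:, 0] - 0.5 * x[:, 3] + rng.normal(0, 0.3, 40)
        ours = pls_fit(x, y, n_components=3)
        sk = PLSRegression(n_components=3, scale=True).fit(x, y)
        pred_ours = ours.predict(x)
        pred_sk = sk.predict(x).ravel()
        assert np.allclose(pred_ours, pred_sk, atol=1e-8)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            pls_fit(np.random.default_rng(0).normal(size=(10, 2)),
                    np.ones(10))


class TestVipPartialR2:
    @pytest.fixture(scope="class")
    def fitted(cls):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(35, 7))
        y = x[:, 0] + 0.5 * x[:, 1] + rng.normal(0, 0.4, 35)
        return pls_fit(x, y, n_components=3)

    def test_partial_r2_sums_to_r2y(self, fitted):
        assert fitted.partial_r2().sum() == pytest.approx(fitted.r2y,
                                                          abs=1e-8)

    def test_partial_r2_equals_r2y_vip2_over_p(self, fitted):
        p = fitted.weights.shape[0]
        expect = fitted.r2y * fitted.vip() ** 2 / p
        assert np.allclose(fitted.partial_r2(), expect, atol=1e-8)

    def test_identical_predictors_share_vip_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=30)
        x = np.tile(base.reshape(-1, 1), (1, 4))
        y = base + rng.normal(0, 0.2, 30)
        res = pls_fit(x, y, n_components=1)
        assert np.allclose(res.vip(), 1.0, atol=1e-10)

    def test_identities_hold_across_random_datasets(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n, p = int(rng.integers(15, 40)), int(rng.integers(2, 9))
            x = rng.normal(size=(n, p))
            y = x @ rng.normal(size=p) + rng.normal(0, 0.5, n)
            res = pls_fit(x, y,
                          n_components=int(rng.integers(1, min(p, 4) + 1)))
            assert res.partial_r2().sum() == pytest.approx(res.r2y, abs=1e-8)
            expect = res.r2y * res.vip() ** 2 / p
            assert np.allclose(res.partial_r2(), expect, atol=1e-8)


class TestPermutation:
    def test_deterministic_relationship_minimal_p(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        y = 2.0 * x.ravel()
        out = pls_permutation_test(x, y, n_perm=99, seed=0)
        assert out["p_r2y"] == pytest.approx(1 / 100)

    def test_independent_response_large_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        out = pls_permutation_test(x, y, n_perm=199, seed=1)
        assert out["p_r2y"] > 0.05

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 2))
        y = x[:, 0] + rng.normal(0, 1, 20)
        a = pls_permutation_test(x, y, n_perm=99, seed=3)
        b = pls_permutation_test(x, y, n_perm=99, seed=3)
        assert a == b


class TestForwardSelection:
    def test_single_loading_predictor_found(self):
        hits = 0
        for seed in range(20):
            cfg = SynthConfig(seed=seed)
            x, y, mask = make_pls_dataset(cfg, n_samples=40, n_predictors=5,
                                          n_loading=1, noise_sd=0.25)
            selected, model = forward_select_pls(x, y, n_perm=99, seed=seed)
            if selected and selected[0] == "x0":
                hits += 1
        assert hits >= 16  # the truly loading predictor leads the selection

    def test_pure_noise_rarely_selected(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = pd.DataFrame(rng.normal(size=(30, 4)),
                             columns=[f"x{j}" for j in range(4)])
            y = rng.normal(size=30)
            selected, _ = forward_select_pls(x, y, n_perm=99, seed=seed)
            empties += not selected
        assert empties >= 15  # ~(1 - alpha) of null datasets select nothing

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(seed=9)
        x, y, _ = make_pls_dataset(cfg, n_samples=30, n_predictors=4)
        a = forward_select_pls(x, y, n_perm=99, seed=5)[0]
        b = forward_select_pls(x, y, n_perm=99, seed=5)[0]
        assert a == b
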