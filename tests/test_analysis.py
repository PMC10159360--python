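"""Receptive-field estimation, Gaussian plausibility and statistics."""

import numpy as np
import pytest

import hybridsi as hs
from hybridsi.analysis import _svd_factorize


class TestEstimateRF:
    def test_gradient_equals_composed_linear_filter(self):
        """For the factorized model the log-rate is linear in the input, so
        the gradient RF must equal the explicit spatial x temporal x readout
        composition."""
        model = hs.SIModel(hs.SIConfig(n_lags=4), (2, 14, 14), 3, seed=0)
        rf = hs.estimate_rf(model, 1).spatiotemporal  # [C, L, H, W]

        ws = model.spatial.data.astype(np.float64)    # [F, C, 9, 9]
        wt = model.temporal.data.astype(np.float64)   # [F, F, L]
        wr = model.readout.data[1].astype(np.float64).reshape(
            16, model.out_h, model.out_w)
        expected = np.zeros_like(rf)
        for fo in range(16):
            for fi in range(16):
                for lag in range(4):
                    for i in range(model.out_h):
                        for j in range(model.out_w):
                            expected[:, lag, i : i + 9, j : j + 9] += (
                                wr[fo, i, j] * wt[fo, fi, lag] * ws[fi]
                            )
        np.testing.assert_allclose(rf, expected, rtol=1e-4, atol=1e-6)

    def test_rank_one_filter_has_unit_singular_ratio(self):
        rf = np.einsum("l,chw->clhw", np.array([1.0, -2.0, 0.5]),
                       np.random.default_rng(0).normal(size=(2, 6, 6)))
        est = _svd_factorize(rf)
        assert est.singular_value_ratio == pytest.approx(1.0, abs=1e-10)
        recon = np.einsum("l,chw->clhw", est.temporal_component,
                          est.spatial_component)
        np.testing.assert_allclose(recon, rf, atol=1e-10)

    def test_temporal_component_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(1)
        est = _svd_factorize(rng.normal(size=(2, 5, 7, 7)))
        assert np.linalg.norm(est.temporal_component) == pytest.approx(1.0)
        peak = np.argmax(np.abs(est.temporal_component))
        assert est.temporal_component[peak] > 0

    def test_invalid_neuron_index(self):
        model = hs.SIModel(hs.SIConfig(n_lags=4), (2, 14, 14), 3, seed=0)
        with pytest.raises(IndexError):
            hs.estimate_rf(model, 3)


class TestGaussianFit:
    @staticmethod
    def _gaussian(h, w, x0, y0, sx, sy, amp=1.0):
        yy, xx = np.mgrid[0:h, 0:w]
        return amp * np.exp(-0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2))

    def test_exact_gaussian_fits_perfectly(self):
        z = self._gaussian(9, 9, 4.2, 3.8, 2.0, 1.5)
        fit = hs.gaussian_fit_r2(z)
        assert fit.r_squared >= 0.999
        assert fit.center[0] == pytest.approx(4.2, abs=0.1)

    def test_oversized_sigma_forces_zero(self):
        z = self._gaussian(9, 9, 4, 4, 20.0, 20.0)
        assert hs.gaussian_fit_r2(z).r_squared == 0.0

    def test_sign_and_scale_invariance(self):
        z = self._gaussian(9, 9, 4, 5, 2.0, 2.5) + 0.05
        base = hs.gaussian_fit_r2(z).r_squared
        assert hs.gaussian_fit_r2(-z).r_squared == pytest.approx(base, abs=1e-4)
        assert hs.gaussian_fit_r2(7.3 * z).r_squared == pytest.approx(base, abs=1e-4)

    def test_noise_filters_fit_poorly(self):
        rng = np.random.default_rng(2)
        r2 = [hs.gaussian_fit_r2(rng.normal(size=(9, 9)), seed=i).r_squared
              for i in range(30)]
        assert np.median(r2) < 0.5

    def test_constant_filter_defined_as_zero(self):
        assert hs.gaussian_fit_r2(np.full((9, 9), 0.7)).r_squared == 0.0

    def test_range(self):
        rng = np.random.default_rng(3)
        for i in range(10):
            r2 = hs.gaussian_fit_r2(rng.normal(size=(9, 9)), seed=i).r_squared
            assert 0.0 <= r2 <= 1.0


class TestDominantChannel:
    def _est(self, spatial):
        return hs.RFEstimate(spatiotemporal=np.zeros((2, 1, 3, 3)),
                             spatial_component=spatial,
                             temporal_component=np.array([1.0]),
                             singular_value_ratio=1.0)

    def test_stronger_channel_selected(self):
        spatial = np.zeros((2, 3, 3))
        spatial[0, 1, 1] = 10.0
        spatial[1, 1, 1] = -1.0
        assert hs.dominant_channel(self._est(spatial)) == 0
        assert hs.dominant_channel(self._est(spatial[::-1])) == 1

    def test_tie_goes_to_lowest_index(self):
        spatial = np.ones((2, 3, 3))
        assert hs.dominant_channel(self._est(spatial)) == 0


class TestPredictiveCC:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        assert hs.predictive_cc(x, x) == pytest.approx(1.0)
        assert hs.predictive_cc(3.0 * x + 2.0, x) == pytest.approx(1.0)

    def test_independent_traces_near_zero(self):
        rng = np.random.default_rng(5)
        hits = sum(
            abs(hs.predictive_cc(rng.normal(size=1000), rng.normal(size=1000))) < 0.1
            for _ in range(60)
        )
        assert hits >= 54  # ~95% of |CC| < 0.1 under the null

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hs.predictive_cc(np.ones(10), np.arange(10.0))


class TestDSTest:
    def test_uniform_noiseless_tuning_gives_zero_index(self):
        profile = np.exp(-0.5 * ((np.arange(30) - 15) / 4.0) ** 2)
        resp = np.tile(profile[:, None, None], (1, 8, 3))
        trials = hs.DirectionTrials(responses=resp)
        res = hs.ds_test(trials, n_perm=50, seed=0)
        assert res.ds_index == pytest.approx(0.0, abs=1e-8)

    def test_single_direction_response_is_maximally_selective(self):
        resp = np.zeros((30, 8, 3))
        profile = np.exp(-0.5 * ((np.arange(30) - 15) / 4.0) ** 2)
        resp[:, 2, :] = profile[:, None]
        res = hs.ds_test(hs.DirectionTrials(responses=resp), n_perm=200, seed=1)
        assert res.ds_index == pytest.approx(1.0, abs=1e-8)  # unit tuning mass
        assert res.p_value <= 2 / 201

    def test_tuned_cells_detected_untuned_not(self):
        cells = hs.simulate_direction_trials(
            6, [0.0, 0.0, 0.0, 0.9, 0.9, 0.9], n_trials=6, noise_sd=0.1, seed=2)
        ps = [hs.ds_test(c, n_perm=200, seed=3).p_value for c in cells]
        assert all(p > 0.05 for p in ps[:3])
        assert all(p < 0.05 for p in ps[3:])


class TestCompareModels:
    def test_identical_scores_give_p_one(self):
        x = np.random.default_rng(6).normal(size=30)
        assert hs.compare_models(x, x, n_perm=500, seed=0) == 1.0

    def test_huge_offset_gives_minimal_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=40)
        assert hs.compare_models(a + 10.0, a, n_perm=1000, seed=1) == pytest.approx(
            1 / 1001)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hs.compare_models(np.ones(3), np.ones(4))


class TestBootstrapCI:
    def test_constant_vector_degenerate_interval(self):
        lo, hi = hs.bootstrap_ci(np.full(20, 3.5), seed=0)
        assert lo == hi == 3.5

    def test_interval_brackets_the_sample_mean(self):
        rng = np.random.default_rng(8)
        for i in range(20):
            v = rng.normal(size=50)
            lo, hi = hs.bootstrap_ci(v, seed=i)
            assert lo <= v.mean() <= hi

    def test_coverage_of_true_mean(self):
        """~95% of percentile intervals cover the population mean."""
        rng = np.random.default_rng(9)
        n_rep, covered = 400, 0
        for i in range(n_rep):
            v = rng.normal(size=100)
            lo, hi = hs.bootstrap_ci(v, n_boot=300, seed=i)
            covered += lo <= 0.0 <= hi
        assert abs(covered / n_rep - 0.95) < 0.03
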