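"""Statistical and structural contracts of the synthetic-data generators."""

import numpy as np
import pytest

import hybridsi as hs
from hybridsi.analysis import predictive_cc


class TestBinaryNoise:
    def test_values_shape_and_determinism(self):
        m = hs.generate_binary_noise(28, 28, 100, 2, 5.0, seed=0)
        assert m.frames.shape == (100, 2, 28, 28)
        assert set(np.unique(m.frames)) == {-1.0, 1.0}
        m2 = hs.generate_binary_noise(28, 28, 100, 2, 5.0, seed=0)
        np.testing.assert_array_equal(m.frames, m2.frames)

    def test_minimal_case(self):
        m = hs.generate_binary_noise(1, 1, 1, 1, 5.0, seed=0)
        assert m.frames.shape == (1, 1, 1, 1)
        assert abs(m.frames).max() == 1.0

    def test_independence_statistics(self):
        """Per-pixel mean and lag-1 autocorrelation are 0 up to sampling error."""
        n = 10_000
        m = hs.generate_binary_noise(28, 28, n, 2, 5.0, seed=1)
        se = 1.0 / np.sqrt(n)
        assert np.abs(m.frames.mean(axis=0)).max() < 4 * se
        x = m.frames
        lag1 = (x[1:] * x[:-1]).mean(axis=0)
        assert np.abs(lag1).max() < 4 * np.sqrt(1.0 / (n - 1))

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            hs.generate_binary_noise(0, 28, 10, 2, 5.0, seed=0)


class TestStructuredImages:
    def test_spectral_slope_matches_requested_exponent(self):
        corpus = hs.generate_structured_images(120, 28, 28, 1.0, 0.8, seed=0)
        slope = hs.radial_amplitude_slope(corpus.images)
        assert abs(slope + 1.0) < 0.15
        assert np.abs(corpus.images).max() <= 1.0

    def test_white_limit_is_flat(self):
        corpus = hs.generate_structured_images(120, 28, 28, 0.0, 0.0, seed=0,
                                               nonlinearity=False)
        assert abs(hs.radial_amplitude_slope(corpus.images)) < 0.1

    def test_perfect_chromatic_correlation(self):
        corpus = hs.generate_structured_images(5, 16, 16, 1.0, 1.0, seed=2)
        np.testing.assert_allclose(corpus.images[:, 0], corpus.images[:, 1],
                                   atol=1e-10)

    def test_rejects_invalid_correlation(self):
        with pytest.raises(ValueError):
            hs.generate_structured_images(5, 16, 16, 1.0, 1.5, seed=0)


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        """Per-frequency amplitudes survive scrambling up to the per-image
        range-protection scalar (1 for images that stay inside [-1, 1])."""
        corpus = hs.generate_structured_images(4, 20, 20, 1.0, 0.5, seed=3)
        scr = hs.phase_scramble(corpus, seed=0)
        for i in range(4):
            for c in range(2):
                a_in = np.abs(np.fft.fft2(corpus.images[i, c]))
                a_out = np.abs(np.fft.fft2(scr.images[i, c]))
                nz = a_in > 1e-12 * a_in.max()
                ratio = a_out[nz] / a_in[nz]
                # constant ratio across all frequencies = spectrum preserved
                assert ratio.std() / ratio.mean() < 1e-8

    def test_constant_image_is_fixed_point(self):
        const = hs.ImageCorpus(images=np.full((1, 2, 8, 8), 0.5),
                               provenance="structured")
        scr = hs.phase_scramble(const, seed=0)
        np.testing.assert_allclose(scr.images, const.images, atol=1e-12)

    def test_drives_kurtosis_toward_gaussian_but_keeps_slope(self):
        corpus = hs.generate_structured_images(120, 28, 28, 1.0, 0.8, seed=4)
        scr = hs.phase_scramble(corpus, seed=1)
        s_in = hs.radial_amplitude_slope(corpus.images)
        s_out = hs.radial_amplitude_slope(scr.images)
        assert abs(s_in - s_out) < 0.1

        def kurt(imgs):
            x = imgs.ravel()
            x = (x - x.mean()) / x.std()
            return (x**4).mean() - 3.0

        # signed-square images are heavy-tailed; scrambling gaussianizes
        assert kurt(scr.images) < kurt(corpus.images)
        assert abs(kurt(scr.images)) < 1.5


class TestLNPopulation:
    def test_shapes_and_qi(self):
        stim = hs.generate_binary_noise(28, 28, 500, seed=0)
        resp, neurons = hs.simulate_ln_population(5, stim, n_test_repeats=6,
                                                  n_test_frames=50, seed=0)
        n_nontest = 450
        n_train = round(n_nontest * 440 / 480)
        assert resp.train_traces.shape == (5, n_train)
        assert resp.val_traces.shape == (5, n_nontest - n_train)
        assert resp.test_block.shape == (5, 6, 50)
        assert len(neurons) == 5
        assert np.all(resp.qi_noise > 0) and np.all(resp.qi_noise <= 1 + 1e-9)

    def test_noiseless_repeats_are_identical(self):
        stim = hs.generate_binary_noise(16, 16, 300, seed=1)
        tpl = hs.LNTemplate(trial_noise_sd=0.0)
        resp, _ = hs.simulate_ln_population(3, stim, template=tpl, seed=0)
        for i in range(3):
            for r in range(1, resp.test_block.shape[1]):
                np.testing.assert_array_equal(resp.test_block[i, r],
                                              resp.test_block[i, 0])
        np.testing.assert_allclose(resp.qi_noise, 1.0, atol=1e-12)

    def test_sta_recovers_spatial_rf(self):
        """Spike-triggered average of simulated responses matches ground truth.

        This oracle is independent of the encoding models: for an LN cell
        driven by white noise, the STA is proportional to the linear filter.
        """
        stim = hs.generate_binary_noise(20, 20, 6000, n_channels=2, seed=2)
        tpl = hs.LNTemplate(trial_noise_sd=0.3, off_fraction=0.0)
        resp, neurons = hs.simulate_ln_population(
            4, stim, template=tpl, n_test_frames=50, seed=3)
        for i, nrn in enumerate(neurons):
            trace = np.concatenate([resp.train_traces[i], resp.val_traces[i]])
            frames = stim.frames[: len(trace)]
            # temporal-kernel-matched STA over all lags
            sta = np.zeros_like(nrn.spatial_rf)
            for tau, kt in enumerate(nrn.temporal_kernel):
                sta += kt * np.tensordot(trace[tau:], frames[: len(trace) - tau],
                                         axes=(0, 0))
            cc = predictive_cc(sta.ravel(), nrn.spatial_rf.ravel())
            assert abs(cc) > 0.6

    def test_rejects_short_stimulus(self):
        stim = hs.generate_binary_noise(8, 8, 40, seed=0)
        with pytest.raises(ValueError):
            hs.simulate_ln_population(2, stim, n_test_frames=39, seed=0)


class TestStructuredMovie:
    def test_shape_range_and_temporal_correlation(self):
        movie = hs.generate_structured_movie(60, 20, 20, seed=0)
        assert movie.frames.shape == (60, 2, 20, 20)
        assert np.abs(movie.frames).max() <= 1.0
        x = movie.frames.reshape(60, -1)
        ccs = [np.corrcoef(x[t], x[t + 1])[0, 1] for t in range(0, 59, 5)]
        assert np.mean(ccs) > 0.5  # consecutive frames are correlated


class TestDirectionTrials:
    def test_untuned_cell_has_uniform_mean_amplitude(self):
        cells = hs.simulate_direction_trials(1, [0.0], n_trials=50,
                                             noise_sd=0.01, seed=0)
        amps = cells[0].responses.mean(axis=2).max(axis=0)
        assert amps.std() / amps.mean() < 0.05

    def test_fully_tuned_noiseless_cell_peaks_at_preferred(self):
        cells = hs.simulate_direction_trials(1, [1.0], n_trials=2,
                                             noise_sd=0.0, seed=1)
        amps = cells[0].responses.mean(axis=2).max(axis=0)
        assert amps.max() / amps.sum() > 0.5  # concentrated tuning

    def test_rejects_single_trial(self):
        with pytest.raises(ValueError):
            hs.simulate_direction_trials(1, [0.5], n_trials=1, seed=0)


def test_generators_are_seed_deterministic():
    for maker in [
        lambda s: hs.generate_structured_images(3, 12, 12, seed=s).images,
        lambda s: hs.generate_white_noise_images(3, 12, 12, seed=s).images,
        lambda s: hs.generate_structured_movie(5, 12, 12, seed=s).frames,
        lambda s: hs.simulate_direction_trials(2, [0.3, 0.7], seed=s)[0].responses,
    ]:
        np.testing.assert_array_equal(maker(7), maker(7))
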