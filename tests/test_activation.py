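"""GLM activation mapping, ROI trace extraction, and trial epoching."""

import warnings

import numpy as np
import pytest

import rfus
from rfus.doppler import DopplerSeries


def make_series(images, rate=2.5, pitch=100e-6):
    n = images.shape[0]
    return DopplerSeries(images=images,
                         timestamps=(np.arange(n) + 0.5) / rate,
                         block_size=40, n_removed=12, rate=rate,
                         pixel_pitch=pitch)


def planted_series(protocol, amplitude=0.20, noise_sd=0.0, shape=(20, 20),
                   mask=None, seed=0, baseline=2.0):
    """Doppler series whose in-mask pixels follow baseline*(1 + a*regressor)."""
    n = int(round(protocol.total_duration * 2.5))
    times = (np.arange(n) + 0.5) / 2.5
    design = rfus.build_design(protocol, times)
    if mask is None:
        mask = np.zeros(shape, bool)
        mask[5:12, 6:14] = True
    rng = np.random.default_rng(seed)
    images = np.full((n,) + shape, baseline)
    images[:, mask] *= (1.0 + amplitude * design.regressor)[:, None]
    if noise_sd:
        images += rng.normal(0.0, noise_sd * baseline, images.shape)
    return make_series(images), design, mask


class TestCanonicalHrf:
    def test_shape_properties(self):
        dt = 0.1
        h = rfus.canonical_hrf(dt)
        assert h[0] == pytest.approx(0.0, abs=1e-12)
        assert h.max() == pytest.approx(1.0)
        # argmax at the closed-form mode of the gamma density, (a-1)*scale = 5 s
        assert abs(np.argmax(h) * dt - 5.0) <= dt
        # exactly one sign change: positive lobe then undershoot
        signs = np.sign(h[np.abs(h) > 1e-9])
        assert np.sum(np.diff(signs) != 0) == 1

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            rfus.canonical_hrf(0.0)
        with pytest.raises(ValueError):
            rfus.canonical_hrf(1.5)


class TestBuildDesign:
    def test_columns_and_normalization(self, default_protocol):
        times = (np.arange(4150) + 0.5) / 2.5
        d = rfus.build_design(default_protocol, times)
        assert d.X.shape == (4150, 3)
        assert d.regressor.max() == pytest.approx(1.0)
        assert d.X[:, 2].mean() == pytest.approx(0.0, abs=1e-9)
        # one response bump per trial
        above = d.regressor > 0.5
        n_bumps = np.sum(np.diff(above.astype(int)) == 1)
        assert n_bumps == 50

    def test_no_flash_gives_zero_regressor(self):
        protocol = rfus.make_protocol(flash_duration=0.0)
        times = (np.arange(500) + 0.5) / 2.5
        d = rfus.build_design(protocol, times)
        assert np.all(d.regressor == 0)

    def test_nonuniform_times_rejected(self, default_protocol):
        with pytest.raises(ValueError):
            rfus.build_design(default_protocol, np.array([0.0, 0.4, 1.0, 1.2]))


class TestGlmFit:
    def test_planted_rrbv_recovered(self, short_protocol):
        series, design, mask = planted_series(short_protocol, amplitude=0.20,
                                              noise_sd=0.001)
        res = rfus.glm_fit(series, design)
        assert np.all(np.abs(res.rrbv_map[mask] - 20.0) < 1.0)
        assert np.all(np.abs(res.rrbv_map[~mask]) < 1.0)
        assert mask[res.roi_center]

    def test_perfect_fit_z_capped(self, short_protocol):
        n = int(round(short_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        design = rfus.build_design(short_protocol, times)
        images = np.tile(design.regressor[:, None, None], (1, 4, 4)) + 1.0
        res = rfus.glm_fit(make_series(images), design)
        assert np.all(res.zscore_map == pytest.approx(38.0))
        assert res.beta_maps["stimulus"][0, 0] == pytest.approx(1.0)

    def test_zero_variance_pixel_flagged(self, short_protocol):
        series, design, mask = planted_series(short_protocol, noise_sd=0.01)
        series.images[:, 0, 0] = 3.0
        res = rfus.glm_fit(series, design)
        assert res.zero_variance_mask[0, 0]
        assert res.zscore_map[0, 0] == 0.0
        assert res.pvalue_map[0, 0] == 1.0

    def test_residuals_orthogonal_to_design(self, short_protocol):
        series, design, _ = planted_series(short_protocol, noise_sd=0.05)
        res = rfus.glm_fit(series, design)
        n = series.n_images
        Y = series.images.reshape(n, -1)
        beta = np.stack([res.beta_maps[k].ravel() for k in design.names])
        resid = Y - design.X @ beta
        assert np.abs(design.X.T @ resid).max() < 1e-6 * np.abs(Y).max() * n

    def test_linear_drift_does_not_change_stimulus_beta(self, short_protocol):
        series, design, _ = planted_series(short_protocol, noise_sd=0.02)
        res0 = rfus.glm_fit(series, design)
        t = series.timestamps
        drift = (0.3 + 0.01 * t)[:, None, None]
        series_d = make_series(series.images + drift)
        res1 = rfus.glm_fit(series_d, design)
        np.testing.assert_allclose(res1.beta_maps["stimulus"],
                                   res0.beta_maps["stimulus"], atol=1e-8)

    def test_z_monotone_in_planted_amplitude(self, short_protocol):
        zs = []
        for amp in (0.05, 0.10, 0.20):
            series, design, mask = planted_series(short_protocol, amplitude=amp,
                                                  noise_sd=0.05, seed=1)
            res = rfus.glm_fit(series, design)
            zs.append(res.zscore_map[mask].mean())
        assert zs[0] < zs[1] < zs[2]

    def test_roi_lands_on_planted_response(self, short_protocol):
        # peaked response at SNR >= 5: ROI center within 2 px of the centroid
        n = int(round(short_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        design = rfus.build_design(short_protocol, times)
        zz, xx = np.mgrid[:20, :20]
        centroid = np.array([10.0, 11.0])
        amp = 0.5 * np.exp(-((zz - centroid[0]) ** 2 + (xx - centroid[1]) ** 2)
                           / (2 * 2.0 ** 2))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            images = 2.0 * (1.0 + amp * design.regressor[:, None, None])
            images += rng.normal(0.0, 0.1, images.shape)
            res = rfus.glm_fit(make_series(images), design)
            hits += np.hypot(*(np.array(res.roi_center) - centroid)) <= 2.0
        assert hits >= 19

    def test_bonferroni_threshold(self, short_protocol):
        series, design, _ = planted_series(short_protocol, noise_sd=0.01)
        res = rfus.glm_fit(series, design, alpha=0.05)
        assert res.bonferroni_threshold == pytest.approx(0.05 / 400)


class TestRoiTrace:
    def test_constant_series_gives_zero_percent(self, short_protocol):
        images = np.full((int(short_protocol.total_duration * 2.5), 6, 6), 4.0)
        trace = rfus.extract_roi_trace(make_series(images),
                                       np.ones((6, 6), bool), short_protocol)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_single_pixel_mask(self, short_protocol):
        rng = np.random.default_rng(0)
        images = 1.0 + 0.1 * rng.random(
            (int(short_protocol.total_duration * 2.5), 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        series = make_series(images)
        trace = rfus.extract_roi_trace(series, mask, short_protocol)
        base = images[series.timestamps < 45.0, 2, 3].mean()
        np.testing.assert_allclose(trace,
                                   100 * (images[:, 2, 3] - base) / base)

    def test_planted_percent_response(self, short_protocol):
        series, design, mask = planted_series(short_protocol, amplitude=0.20)
        trace = rfus.extract_roi_trace(series, mask, short_protocol)
        assert trace.max() == pytest.approx(20.0, abs=0.5)

    def test_empty_mask_rejected(self, short_protocol):
        series, _, _ = planted_series(short_protocol)
        with pytest.raises(ValueError):
            rfus.extract_roi_trace(series, np.zeros((20, 20), bool))


class TestEpochTrials:
    def test_default_shape_and_axis(self, default_protocol):
        n = int(round(default_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        epochs = rfus.epoch_trials(np.zeros(n), times, default_protocol)
        assert epochs.trials.shape == (50, 77)
        assert np.sum(epochs.time < 0) == 37
        assert epochs.n_dropped == 0

    def test_identical_trials_zero_sem(self, default_protocol):
        n = int(round(default_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        trace = 5.0 * default_protocol.response(times, rfus.wt_hrf())
        epochs = rfus.epoch_trials(trace, times, default_protocol)
        assert np.allclose(epochs.sem, 0.0, atol=1e-9)

    def test_truncated_trial_dropped_with_warning(self, default_protocol):
        n = int(round(default_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        cut = np.searchsorted(times, default_protocol.onsets[-1] + 5.0)
        with pytest.warns(UserWarning, match="dropped 1"):
            epochs = rfus.epoch_trials(np.zeros(cut), times[:cut],
                                       default_protocol)
        assert epochs.trials.shape[0] == 49
        assert epochs.n_dropped == 1

    def test_mean_trial_converges_to_truth_with_trial_count(
            self, default_protocol):
        # RMSE of the mean trial vs the planted response shrinks ~ 1/sqrt(N)
        params = rfus.wt_hrf().scaled(100.0, units="percent")
        n = int(round(default_protocol.total_duration * 2.5))
        times = (np.arange(n) + 0.5) / 2.5
        rng = np.random.default_rng(0)
        clean = 100 * default_protocol.response(times, rfus.wt_hrf())
        rmse = {}
        for n_avg in (5, 45):
            errs = []
            for rep in range(8):
                trace = clean + rng.normal(0, 8.0, n)
                ep = rfus.epoch_trials(trace, times, default_protocol)
                idx = rng.integers(0, 50, n_avg)
                mean_trial = ep.trials[idx].mean(axis=0)
                truth = rfus.four_cosine_eval(params, ep.time)
                truth = truth - truth[ep.time < 0].mean()
                errs.append(np.sqrt(np.mean((mean_trial - truth) ** 2)))
            rmse[n_avg] = np.mean(errs)
        assert rmse[45] < rmse[5] / 2.0
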