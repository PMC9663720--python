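"""GLM activation mapping, ROI extraction and trial epoching.

Each pixel's power-Doppler time course is regressed on a stimulus regressor
(the flash boxcar convolved with the canonical double-gamma HRF), a constant,
and a linear trend (equivalent to linear detrending).  The z-score map is the
normal-quantile transform of the per-pixel t statistic; the relative
blood-volume map (rRBV) expresses the stimulus coefficient as a percent of the
constant term at the regressor peak.  A circular region of interest (1.4 mm
diameter by default) is placed automatically on the peak z-score, its mean
trace converted to percent of baseline, and the trace cut into per-trial
epochs aligned on the flash onsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .doppler import DopplerSeries
from .synthetic import StimulusProtocol

__all__ = [
    "DesignMatrix", "ActivationResult", "TrialEpochs",
    "canonical_hrf", "build_design", "glm_fit", "extract_roi_trace",
    "epoch_trials",
]

Z_MAX = 38.0  # double-precision tail limit for the normal quantile


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds, unit peak.

    Difference of two gamma densities: response peak at 6 s, undershoot peak
    at 16 s, peak-to-undershoot ratio 6, both with unit dispersion; kernel
    length 32 s.
    """
    if not 0 < dt <= 1.0:
        raise ValueError(f"dt must be in (0, 1] s, got {dt}")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, a=6, scale=1) - stats.gamma.pdf(t, a=16, scale=1) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Three-column GLM design: stimulus regressor, constant, linear trend."""

    X: np.ndarray            # (n, 3)
    sample_times: np.ndarray
    names: tuple[str, ...] = ("stimulus", "constant", "trend")

    @property
    def regressor(self) -> np.ndarray:
        return self.X[:, 0]


def build_design(protocol: StimulusProtocol,
                 series_times: np.ndarray) -> DesignMatrix:
    """Stimulus boxcar convolved with the canonical HRF, plus constant and trend.

    The regressor is normalized to unit peak; the trend column is zero-mean.
    ``series_times`` must be uniformly spaced (the Doppler frame grid).
    """
    times = np.asarray(series_times, float)
    if times.size < 2:
        raise ValueError("need at least 2 sample times")
    dts = np.diff(times)
    dt = float(dts[0])
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("series_times must be uniformly spaced")
    boxcar = protocol.boxcar(times)
    kernel = canonical_hrf(dt)
    reg = np.convolve(boxcar, kernel)[: times.size]
    peak = reg.max()
    if peak > 0:
        reg = reg / peak
    trend = times - times.mean()
    X = np.column_stack([reg, np.ones_like(times), trend])
    return DesignMatrix(X=X, sample_times=times)


@dataclass
class ActivationResult:
    beta_maps: dict[str, np.ndarray]
    zscore_map: np.ndarray
    pvalue_map: np.ndarray
    rrbv_map: np.ndarray          # percent
    roi_center: tuple[int, int]
    roi_mask: np.ndarray
    threshold_alpha: float
    zero_variance_mask: np.ndarray

    @property
    def bonferroni_threshold(self) -> float:
        """Per-pixel p threshold: alpha divided by the number of pixels tested."""
        return self.threshold_alpha / self.zscore_map.size

    @property
    def significant_mask(self) -> np.ndarray:
        return self.pvalue_map < self.bonferroni_threshold


def _disc_mask(shape: tuple[int, int], center: tuple[int, int],
               diameter_px: float) -> np.ndarray:
    zz, xx = np.mgrid[: shape[0], : shape[1]]
    r2 = (zz - center[0]) ** 2 + (xx - center[1]) ** 2
    return r2 <= (diameter_px / 2.0) ** 2


def glm_fit(
    series: DopplerSeries,
    design: DesignMatrix,
    alpha: float = 0.05,
    roi_diameter_m: float = 1.4e-3,
) -> ActivationResult:
    """Per-pixel ordinary least squares of the Doppler series on the design.

    z is the signed normal quantile of the t tail probability (df = n - 3),
    capped at +/-38; p is the two-sided normal tail of z.  rRBV is
    ``100 * beta_stim * max(regressor) / beta_const``.  The ROI is a disc of
    ``roi_diameter_m`` centered on the z argmax (first occurrence in
    row-major order on ties).  Zero-variance pixels get z = 0, p = 1 and are
    flagged, not raised.
    """
    X = design.X
    n, p = X.shape
    if series.n_images != n:
        raise ValueError(
            f"series length {series.n_images} != design rows {n}")
    if n < 10:
        raise ValueError("need at least 10 samples for the GLM")
    nz, nx = series.images.shape[1:]
    Y = series.images.reshape(n, nz * nx)

    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    sse = np.sum(resid ** 2, axis=0)
    xtx_inv = np.linalg.inv(X.T @ X)
    var_scale = xtx_inv[0, 0]

    zero_var = Y.std(axis=0) <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df * var_scale)
        tval = beta[0] / se
    # perfect fits (se == 0, beta != 0) -> saturate; zero-variance -> neutral
    tval = np.where(np.isfinite(tval), tval, np.sign(beta[0]) * np.inf)
    with np.errstate(over="ignore"):
        tail = np.exp(stats.t.logsf(np.abs(tval), df))
    z_abs = stats.norm.isf(tail)
    z_abs = np.where(np.isfinite(z_abs), z_abs, Z_MAX)
    z = np.sign(tval) * np.clip(z_abs, 0.0, Z_MAX)
    z[zero_var] = 0.0
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval[zero_var] = 1.0

    with np.errstate(divide="ignore", invalid="ignore"):
        rrbv = 100.0 * beta[0] * design.regressor.max() / beta[1]
    rrbv = np.where(np.isfinite(rrbv), rrbv, 0.0)

    zmap = z.reshape(nz, nx)
    center = np.unravel_index(int(np.argmax(zmap)), zmap.shape)
    diameter_px = roi_diameter_m / series.pixel_pitch
    roi = _disc_mask((nz, nx), center, diameter_px)

    return ActivationResult(
        beta_maps={name: beta[i].reshape(nz, nx)
                   for i, name in enumerate(design.names)},
        zscore_map=zmap,
        pvalue_map=pval.reshape(nz, nx),
        rrbv_map=rrbv.reshape(nz, nx),
        roi_center=(int(center[0]), int(center[1])),
        roi_mask=roi,
        threshold_alpha=alpha,
        zero_variance_mask=zero_var.reshape(nz, nx),
    )


def extract_roi_trace(
    series: DopplerSeries,
    roi_mask: np.ndarray,
    protocol: StimulusProtocol | None = None,
) -> np.ndarray:
    """ROI-mean Doppler trace as percent change relative to baseline.

    The spatial mean over the mask is taken per Doppler frame and converted
    to percent change relative to the mean over the pre-stimulation baseline
    samples (times before ``protocol.baseline_duration``); without a protocol
    the whole-trace mean serves as baseline.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("roi_mask must be nonempty")
    raw = series.images[:, roi_mask].mean(axis=1)
    if protocol is not None:
        base_samples = series.timestamps < protocol.baseline_duration
        if not base_samples.any():
            raise ValueError("no samples fall in the baseline period")
        baseline = raw[base_samples].mean()
    else:
        baseline = raw.mean()
    if baseline == 0:
        return np.zeros_like(raw)
    return 100.0 * (raw - baseline) / baseline


@dataclass
class TrialEpochs:
    """Per-trial windows of the ROI trace, aligned on the flash onsets."""

    trials: np.ndarray       # (n_trials_kept, n_samples)
    time: np.ndarray         # within-trial axis, seconds relative to onset
    n_dropped: int

    @property
    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.trials.shape[0] < 2:
            return np.zeros(self.trials.shape[1])
        return self.trials.std(axis=0, ddof=1) / np.sqrt(self.trials.shape[0])


def epoch_trials(
    trace: np.ndarray,
    timestamps: np.ndarray,
    protocol: StimulusProtocol,
    pre: float = 14.8,
    post: float = 16.0,
) -> TrialEpochs:
    """Cut the ROI trace into per-trial epochs and re-baseline each trial.

    Each trial's window is [onset - pre, onset + post) on the Doppler grid
    (77 samples of 0.4 s for the default protocol); each trial is
    re-baselined by subtracting the mean of its own pre-onset samples.
    Trials whose window would be truncated are dropped with a warning.
    """
    trace = np.asarray(trace, float)
    timestamps = np.asarray(timestamps, float)
    epochs, rel_time = [], None
    n_dropped = 0
    expected = None
    for onset in protocol.onsets:
        m = (timestamps >= onset - pre) & (timestamps < onset + post)
        idx = np.flatnonzero(m)
        if expected is None:
            dt = timestamps[1] - timestamps[0]
            expected = int(round((pre + post) / dt))
        if idx.size != expected:
            n_dropped += 1
            continue
        window = trace[idx]
        t_rel = timestamps[idx] - onset
        pre_mask = t_rel < 0
        window = window - window[pre_mask].mean()
        epochs.append(window)
        if rel_time is None:
            rel_time = t_rel
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} truncated trial(s)", stacklevel=2)
    if not epochs:
        raise ValueError("no complete trial windows inside the trace")
    return TrialEpochs(trials=np.array(epochs), time=rel_time,
                       n_dropped=n_dropped)
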