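"""Synthetic retinal functional-ultrasound and microbubble data with known ground truth.

No public acquisitions exist for this kind of experiment, so every input of
the analysis chain is generated here with a full ground-truth record:

* compound plane-wave movies whose complex blood signal is a circular Gaussian
  process confined to a vessel mask, with per-frame variance modulated by a
  planted four-cosine hemodynamic response triggered at every flash onset;
* a low-rank "tissue" clutter component (smooth spatial patterns times slow
  temporal courses) at much larger amplitude than blood, which is what the SVD
  clutter filter exists to remove;
* white complex noise;
* single-pixel blood-volume traces (the fast path for statistical experiments
  that do not need the image stages);
* microbubble movies for localization microscopy — point-like Gaussian spots
  flowing along polyline vessels at planted speeds.

All randomness flows from one seed through deterministically spawned
sub-streams, so every simulator is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hrf import HRFParams, four_cosine_eval

__all__ = [
    "StimulusProtocol", "GroundTruth", "CompoundMovie", "BubbleTrajectory",
    "make_protocol", "compound_frame_rate", "simulate_fus_movie",
    "simulate_roi_series", "simulate_ulm_movie",
    "default_truth", "wt_hrf", "tg_hrf", "straight_vessel", "cra_path",
    "SCALED_FRAME_RATE", "SCALED_BLOCK_SIZE", "SCALED_N_REMOVED", "SCALED_SHAPE",
]

DOPPLER_RATE = 2.5  # Hz, compound frame rate / block size at any scale

# Scaled acquisition preset: preserves the Doppler rate (2.5 Hz), the fraction
# of singular values removed (30%) and tissue_rank << n_removed, at a problem
# size that runs in seconds instead of hours.
SCALED_FRAME_RATE = 100.0
SCALED_BLOCK_SIZE = 40
SCALED_N_REMOVED = 12
SCALED_SHAPE = (32, 32)


def compound_frame_rate(prf_hz: float, n_angles: int) -> float:
    """Compound-image frame rate from the plane-wave PRF and angle count.

    Each compound frame sums the echoes of one group of tilted plane waves,
    so e.g. 11 angles fired at 5.5 kHz give 500 Hz and 5 angles at 5 kHz
    give 1000 Hz.
    """
    if prf_hz <= 0 or n_angles < 1:
        raise ValueError("prf_hz must be > 0 and n_angles >= 1")
    return prf_hz / n_angles


@dataclass(frozen=True)
class StimulusProtocol:
    """Visual-stimulation block design: baseline, repeated flash trials, recovery.

    Defaults reproduce the standard acquisition: 45 s baseline, 50 trials of
    (15 s OFF, 0.8 s flash ON, 15 s OFF), 75 s recovery — 1660 s in total.
    """

    baseline_duration: float = 45.0
    n_trials: int = 50
    pre_off: float = 15.0
    flash_duration: float = 0.8
    post_off: float = 15.0
    recovery_duration: float = 75.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "pre_off", "flash_duration",
                     "post_off", "recovery_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")

    @property
    def trial_duration(self) -> float:
        return self.pre_off + self.flash_duration + self.post_off

    @property
    def total_duration(self) -> float:
        return (self.baseline_duration + self.n_trials * self.trial_duration
                + self.recovery_duration)

    @property
    def onsets(self) -> np.ndarray:
        """Flash onset times (s): baseline + pre_off + k * trial_duration."""
        k = np.arange(self.n_trials)
        return self.baseline_duration + self.pre_off + k * self.trial_duration

    def boxcar(self, times: np.ndarray) -> np.ndarray:
        """Stimulus indicator sampled at ``times`` (1 during a flash, else 0)."""
        times = np.asarray(times, float)
        out = np.zeros(times.shape)
        for onset in self.onsets:
            out[(times >= onset) & (times < onset + self.flash_duration)] = 1.0
        return out

    def response(self, times: np.ndarray, params: HRFParams) -> np.ndarray:
        """Superposition of one HRF per flash onset, sampled at ``times``."""
        times = np.asarray(times, float)
        out = np.zeros(times.shape)
        for onset in self.onsets:
            rel = times - onset
            m = (rel >= 0) & (rel <= params.support)
            if m.any():
                out[m] += four_cosine_eval(params, rel[m])
        return out


def make_protocol(**overrides: float) -> StimulusProtocol:
    """Build a stimulation protocol, overriding any of the default durations."""
    return StimulusProtocol(**overrides)


def wt_hrf() -> HRFParams:
    """Ground-truth HRF preset for a wild-type-like response (21% amplitude).

    Timing (rise 2 s, fall 5 s) gives a fast, retina-like transient that
    still overlaps the canonical double-gamma kernel enough for GLM
    detection — a response nearly orthogonal to the canonical regressor
    could not have produced the activation maps the method is built on.
    """
    return HRFParams(delay=0.4, rise_time=2.0, amplitude=0.21,
                     fall_time=5.0, undershoot=0.02, return_time=6.0,
                     units="fraction")


def tg_hrf() -> HRFParams:
    """Transgenic-like preset: identical timing, larger amplitude (37%)."""
    return replace(wt_hrf(), amplitude=0.37)


@dataclass
class GroundTruth:
    """Everything planted in a simulated acquisition.

    ``baseline_blood_power`` may be a scalar (uniform inside the vessel mask)
    or a per-pixel map.  ``tissue_rank`` must stay below the number of
    singular values the clutter filter removes so the filter can cancel the
    clutter completely.
    """

    hrf_params_true: HRFParams
    vessel_mask: np.ndarray
    baseline_blood_power: float | np.ndarray = 1.0
    tissue_rank: int = 2
    noise_sd: float = 0.05
    rng_seed: int = 0
    tissue_amplitude_factor: float = 20.0

    def __post_init__(self) -> None:
        self.vessel_mask = np.asarray(self.vessel_mask, bool)
        if not self.vessel_mask.any():
            raise ValueError("vessel_mask must be nonempty")
        if self.hrf_params_true.amplitude < 0:
            raise ValueError("true HRF amplitude must be >= 0")
        if self.noise_sd < 0 or self.tissue_rank < 0:
            raise ValueError("noise_sd and tissue_rank must be >= 0")

    def power_map(self) -> np.ndarray:
        p = np.zeros(self.vessel_mask.shape)
        p[self.vessel_mask] = np.broadcast_to(
            np.asarray(self.baseline_blood_power, float),
            self.vessel_mask.shape)[self.vessel_mask]
        return p


def default_truth(
    amplitude: float = 0.21,
    shape: tuple[int, int] = SCALED_SHAPE,
    seed: int = 0,
    tissue_rank: int = 2,
    noise_sd: float = 0.05,
    baseline_blood_power: float = 1.0,
    vessel_radius: float | None = None,
) -> GroundTruth:
    """Convenience ground truth: a central circular vascular bed.

    The vessel blob diameter exceeds the 1.4 mm analysis region at the default
    100 um pitch, so the ROI placed on the activation peak is dominated by
    vessel pixels.
    """
    nz, nx = shape
    if vessel_radius is None:
        vessel_radius = min(nz, nx) / 4.0
    zz, xx = np.mgrid[:nz, :nx]
    mask = (zz - nz / 2) ** 2 + (xx - nx / 2) ** 2 <= vessel_radius ** 2
    base = wt_hrf()
    return GroundTruth(
        hrf_params_true=base.scaled(amplitude / base.amplitude),
        vessel_mask=mask,
        baseline_blood_power=baseline_blood_power,
        tissue_rank=tissue_rank,
        noise_sd=noise_sd,
        rng_seed=seed,
    )


@dataclass
class CompoundMovie:
    """Time-ordered stack of ultrafast compound frames on a fixed spatial grid.

    ``frames`` has shape (n_frames, nz, nx); complex-valued for blood-flow
    movies (analytic/IQ convention, power = squared magnitude), real-valued
    for microbubble envelope movies.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float = 100e-6
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, nz, nx)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


def _smooth_pattern(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smooth random spatial field with unit RMS (low-pass white noise)."""
    from scipy.ndimage import gaussian_filter
    f = gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 8)
    return f / np.sqrt(np.mean(f ** 2))


def simulate_fus_movie(
    protocol: StimulusProtocol,
    truth: GroundTruth,
    shape: tuple[int, int] = (128, 100),
    frame_rate: float = 500.0,
    pixel_pitch: float = 100e-6,
    dtype: np.dtype = np.complex64,
    _chunk: int = 20000,
) -> tuple[CompoundMovie, GroundTruth]:
    """Simulate a compound plane-wave movie: tissue clutter + blood + noise.

    Blood is a temporally white circular complex Gaussian confined to the
    vessel mask, with per-frame variance ``baseline_blood_power * (1 + h(t))``
    where ``h`` is the planted HRF triggered at every flash onset (so power
    Doppler tracks blood volume).  Tissue is an exactly rank-``tissue_rank``
    component — smooth spatial patterns times slow (< 0.2 Hz) temporal
    courses — scaled to ``tissue_amplitude_factor`` times the RMS blood
    amplitude.  Noise is white circular complex Gaussian with standard
    deviation ``noise_sd`` per complex sample.

    Frames are filled in time chunks to bound peak memory.
    """
    nz, nx = shape
    if nz < 32 or nx < 32:
        raise ValueError("grid must be at least 32x32")
    if truth.vessel_mask.shape != shape:
        raise ValueError(
            f"vessel_mask shape {truth.vessel_mask.shape} != grid {shape}")

    n_frames = int(round(protocol.total_duration * frame_rate))
    times = np.arange(n_frames) / frame_rate
    h = protocol.response(times, truth.hrf_params_true)

    ss = np.random.SeedSequence(truth.rng_seed)
    rng_tissue, rng_blood, rng_noise = [np.random.default_rng(s)
                                        for s in ss.spawn(3)]

    mask = truth.vessel_mask
    n_vessel = int(mask.sum())
    power = truth.power_map()[mask]  # (n_vessel,)
    blood_rms = math.sqrt(float(np.mean(power))) if n_vessel else 0.0

    # tissue: rank-k outer products, built once (cheap: k small)
    tissue_patterns = []
    tissue_courses = []
    for r in range(truth.tissue_rank):
        pat = (_smooth_pattern(rng_tissue, shape)
               + 1j * _smooth_pattern(rng_tissue, shape))
        f_r = 0.02 + 0.06 * r  # Hz, slow drift-like motion
        phase = rng_tissue.uniform(0, 2 * np.pi)
        course = 1.0 + 0.3 * np.cos(2 * np.pi * f_r * times + phase)
        amp = truth.tissue_amplitude_factor * max(blood_rms, truth.noise_sd, 1e-12)
        amp *= 1.0 + 0.5 * r  # distinct scales -> well-separated singular values
        tissue_patterns.append(amp * pat / np.sqrt(np.mean(np.abs(pat) ** 2)))
        tissue_courses.append(course / np.sqrt(np.mean(course ** 2)))

    movie = np.empty((n_frames, nz, nx), dtype=dtype)
    flat_mask = mask.ravel()
    for start in range(0, n_frames, _chunk):
        sl = slice(start, min(start + _chunk, n_frames))
        nt = sl.stop - sl.start
        if truth.noise_sd > 0:
            chunk = rng_noise.standard_normal(
                nt * nz * nx * 2, dtype=np.float32).view(np.complex64)
            chunk = (truth.noise_sd / math.sqrt(2)) * chunk.reshape(nt, nz * nx)
            chunk = chunk.astype(dtype, copy=False)
        else:
            chunk = np.zeros((nt, nz * nx), dtype=dtype)
        if n_vessel:
            sigma = np.sqrt(np.outer(1.0 + h[sl], power) / 2.0).astype(np.float32)
            blood = rng_blood.standard_normal(
                nt * n_vessel * 2, dtype=np.float32).view(np.complex64)
            chunk[:, flat_mask] += (sigma * blood.reshape(nt, n_vessel)).astype(
                dtype, copy=False)
        for pat, course in zip(tissue_patterns, tissue_courses):
            chunk += (course[sl].astype(np.float32)[:, None]
                      * pat.ravel().astype(np.complex64)[None, :]).astype(
                          dtype, copy=False)
        movie[sl] = chunk.reshape(nt, nz, nx)

    return CompoundMovie(movie, frame_rate, pixel_pitch), truth


def simulate_roi_series(
    protocol: StimulusProtocol,
    truth: GroundTruth,
    n_animals: int = 1,
    between_animal_sd: float = 0.0,
    rate: float = DOPPLER_RATE,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single-pixel fast path: per-animal blood-volume traces at the Doppler rate.

    Bypasses the image stages for statistical experiments.  Each animal's
    trace is ``1 + h_a(t) + noise`` where the animal's response amplitude is
    drawn as ``A_true * (1 + Normal(0, between_animal_sd))`` and the additive
    noise has standard deviation ``truth.noise_sd`` per sample (units:
    fraction of the unit baseline).

    Returns
    -------
    times : (n_samples,) array — block-center timestamps.
    traces : (n_animals, n_samples) array.
    record : dict with the planted per-animal amplitudes and the seed.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    n = int(round(protocol.total_duration * rate))
    times = (np.arange(n) + 0.5) / rate
    ss = np.random.SeedSequence(truth.rng_seed)
    amplitudes = np.empty(n_animals)
    traces = np.empty((n_animals, n))
    for a, child in enumerate(ss.spawn(n_animals)):
        rng = np.random.default_rng(child)
        amp = truth.hrf_params_true.amplitude * (
            1.0 + rng.normal(0.0, between_animal_sd))
        amp = max(amp, 0.0)
        amplitudes[a] = amp
        params = replace(truth.hrf_params_true, amplitude=amp,
                         undershoot=min(truth.hrf_params_true.undershoot, amp))
        traces[a] = 1.0 + protocol.response(times, params)
        if truth.noise_sd > 0:
            traces[a] += rng.normal(0.0, truth.noise_sd, n)
    record = {"amplitudes_true": amplitudes, "rng_seed": truth.rng_seed,
              "between_animal_sd": between_animal_sd, "rate": rate}
    return times, traces, record


# ---------------------------------------------------------------------------
# microbubble movies for localization microscopy

@dataclass
class BubbleTrajectory:
    """True sub-pixel positions of one simulated bubble, one row per frame."""

    frames: np.ndarray    # frame indices
    positions: np.ndarray # (n, 2) as (z, x) in pixels
    speed: float          # planted speed, mm/s


def straight_vessel(start: tuple[float, float], stop: tuple[float, float],
                    speed: float) -> dict:
    """A straight polyline vessel carrying bubbles at ``speed`` mm/s."""
    return {"points": np.array([start, stop], float), "speed": float(speed)}


def cra_path(shape: tuple[int, int] = (64, 64), speed: float = 20.0) -> dict:
    """Straight central-retinal-artery-like vessel preset (default 20 mm/s)."""
    nz, nx = shape
    return straight_vessel((nz * 0.5, nx * 0.1), (nz * 0.5, nx * 0.9), speed)


def simulate_ulm_movie(
    vessel_paths: list[dict],
    bubble_rate: float = 5.0,
    psf_sigma: float = 1.2,
    n_frames: int = 1000,
    frame_rate: float = 1000.0,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch: float = 100e-6,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CompoundMovie, list[BubbleTrajectory]]:
    """Simulate a microbubble movie for localization microscopy.

    Bubbles appear at each path's start at Poisson times (``bubble_rate`` per
    second per path), advance along the polyline at the path's constant
    planted speed, and are rendered as isotropic Gaussian spots of standard
    deviation ``psf_sigma`` pixels and peak ``amplitude``.  Returns the movie
    and the exact per-frame trajectories.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    nz, nx = shape
    for path in vessel_paths:
        pts = np.asarray(path["points"], float)
        if path["speed"] < 0:
            raise ValueError("vessel speed must be >= 0")
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > nz - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > nx - 1):
            raise ValueError("vessel path lies outside the grid")

    rng = np.random.default_rng(seed)
    mm_per_px = pixel_pitch * 1e3
    duration = n_frames / frame_rate

    # spawn times per path
    bubbles: list[tuple[np.ndarray, float, float]] = []  # (points, speed, t_spawn)
    for path in vessel_paths:
        pts = np.asarray(path["points"], float)
        t = 0.0
        while True:
            t += rng.exponential(1.0 / bubble_rate) if bubble_rate > 0 else np.inf
            if t >= duration:
                break
            bubbles.append((pts, float(path["speed"]), t))

    # precompute arc-length parameterisation per bubble and its per-frame positions
    trajectories: list[BubbleTrajectory] = []
    per_frame_spots: list[list[tuple[float, float]]] = [[] for _ in range(n_frames)]
    for pts, speed, t_spawn in bubbles:
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])  # pixels
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total_len = cum[-1]
        speed_px = speed / mm_per_px  # px per second
        first = int(np.ceil(t_spawn * frame_rate))
        frames, positions = [], []
        for f in range(first, n_frames):
            s = speed_px * (f / frame_rate - t_spawn)
            if s > total_len:
                break
            i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg_len) - 1)
            frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
            pos = pts[i] + frac * seg[i]
            frames.append(f)
            positions.append(pos)
            per_frame_spots[f].append((pos[0], pos[1]))
        if frames:
            trajectories.append(BubbleTrajectory(
                np.array(frames), np.array(positions), speed))

    movie = np.zeros((n_frames, nz, nx), dtype=np.float64)
    if noise_sd > 0:
        movie += rng.normal(0.0, noise_sd, movie.shape)
    w = int(np.ceil(4 * psf_sigma))
    for f, spots in enumerate(per_frame_spots):
        for (zc, xc) in spots:
            z0, z1 = max(int(zc) - w, 0), min(int(zc) + w + 1, nz)
            x0, x1 = max(int(xc) - w, 0), min(int(xc) + w + 1, nx)
            zz, xx = np.mgrid[z0:z1, x0:x1]
            movie[f, z0:z1, x0:x1] += amplitude * np.exp(
                -((zz - zc) ** 2 + (xx - xc) ** 2) / (2 * psf_sigma ** 2))

    return CompoundMovie(movie, frame_rate, pixel_pitch), trajectories
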