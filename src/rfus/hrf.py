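"""Parametric hemodynamic response model built from four half-period cosines.

The retinal blood-volume transient evoked by a brief light flash is modelled
as a piecewise curve assembled from four half-cosines and parameterized by six
physiologically interpretable quantities:

* ``delay`` (t0)            — latency between stimulus onset and response onset
* ``rise_time`` (tr)        — duration of the rise from baseline to the peak
* ``amplitude`` (A)         — peak response above baseline
* ``fall_time`` (tf)        — duration of the decay from the peak back to baseline
* ``undershoot`` (Au)       — depth of the post-response undershoot (>= 0)
* ``return_time`` (tb)      — duration of the undershoot lobe (descent + return)

The curve is 0 for t < t0, rises 0 -> A over [t0, t0+tr] (half cosine), falls
A -> 0 over tf, descends 0 -> -Au over tb/2, returns -Au -> 0 over the second
tb/2, and is 0 afterwards.  It is C0-continuous everywhere, which is what makes
constrained least-squares fitting well behaved.

Fitting uses bound-constrained least squares with deterministic multi-starts
(a data-driven start plus a seeded Latin-hypercube of the box).  The undershoot
is parameterized internally as a fraction of the amplitude so that the
constraint 0 <= Au <= A is a plain box constraint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = ["HRFParams", "FitResult", "four_cosine_eval", "fit_hrf", "DEFAULT_BOUNDS"]


@dataclass(frozen=True)
class HRFParams:
    """Six parameters of the four-half-cosine response model.

    Times are in seconds; ``amplitude`` and ``undershoot`` share one unit
    (percent of baseline by convention, fraction for simulation ground truth —
    recorded in ``units``).
    """

    delay: float
    rise_time: float
    amplitude: float
    fall_time: float
    undershoot: float
    return_time: float
    units: str = "percent"

    def validate(self) -> None:
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")
        for name in ("rise_time", "fall_time", "return_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 <= self.undershoot <= max(self.amplitude, 0):
            raise ValueError(
                f"undershoot must lie in [0, amplitude], got {self.undershoot}"
            )

    @property
    def support(self) -> float:
        """Total duration of the non-zero part of the response (s)."""
        return self.delay + self.rise_time + self.fall_time + self.return_time

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.delay, self.rise_time, self.amplitude,
             self.fall_time, self.undershoot, self.return_time]
        )

    def scaled(self, factor: float, units: str | None = None) -> "HRFParams":
        """Scale the two amplitude parameters (e.g. fraction <-> percent)."""
        return dataclasses.replace(
            self,
            amplitude=self.amplitude * factor,
            undershoot=self.undershoot * factor,
            units=units if units is not None else self.units,
        )


@dataclass
class FitResult:
    params: HRFParams
    sse: float
    n_restarts_used: int
    converged: bool
    bounds_active: list[str]


def four_cosine_eval(params: HRFParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the four-half-cosine response at times ``t`` since stimulus onset.

    Vectorized over ``t``; returns 0 outside the response support.
    """
    params.validate()
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    t0, tr, a, tf, au, tb = (
        params.delay, params.rise_time, params.amplitude,
        params.fall_time, params.undershoot, params.return_time,
    )
    out = np.zeros_like(t)

    # rise: 0 -> A
    m = (t >= t0) & (t < t0 + tr)
    out[m] = a * 0.5 * (1.0 - np.cos(np.pi * (t[m] - t0) / tr))
    # fall: A -> 0
    e1 = t0 + tr
    m = (t >= e1) & (t < e1 + tf)
    out[m] = a * 0.5 * (1.0 + np.cos(np.pi * (t[m] - e1) / tf))
    # undershoot descent: 0 -> -Au over tb/2
    e2 = e1 + tf
    half = tb / 2.0
    m = (t >= e2) & (t < e2 + half)
    out[m] = -au * 0.5 * (1.0 - np.cos(np.pi * (t[m] - e2) / half))
    # undershoot return: -Au -> 0 over tb/2
    e3 = e2 + half
    m = (t >= e3) & (t < e3 + half)
    out[m] = -au * 0.5 * (1.0 + np.cos(np.pi * (t[m] - e3) / half))

    return out[0] if scalar else out


# box bounds (seconds / response units): delay, rise, amplitude, fall,
# undershoot-to-amplitude ratio, return time
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "delay": (0.0, 3.0),
    "rise_time": (0.2, 10.0),
    "amplitude": (0.0, 200.0),
    "fall_time": (0.2, 15.0),
    "undershoot_ratio": (0.0, 1.0),
    "return_time": (0.2, 15.0),
}

_PARAM_ORDER = ("delay", "rise_time", "amplitude", "fall_time",
                "undershoot_ratio", "return_time")


def _vector_to_params(x: np.ndarray, units: str) -> HRFParams:
    t0, tr, a, tf, ratio, tb = x
    return HRFParams(t0, tr, a, tf, ratio * a, tb, units=units)


def _residual(x: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return four_cosine_eval(_vector_to_params(x, "percent"), t) - y


def fit_hrf(
    t: np.ndarray,
    y: np.ndarray,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    x0: np.ndarray | None = None,
    units: str = "percent",
) -> FitResult:
    """Fit the four-cosine model to a mean-trial response by constrained least squares.

    Parameters
    ----------
    t
        Sample times in seconds relative to stimulus onset (may include
        negative, pre-stimulus samples — the model is zero there).
    y
        Response values (same units as the fitted amplitude, typically
        percent of baseline).
    bounds
        Box bounds per parameter name; defaults to :data:`DEFAULT_BOUNDS`.
        The undershoot bound is expressed as a ratio of the amplitude so the
        physiological constraint ``0 <= Au <= A`` stays a box.
    n_restarts
        Number of deterministic multi-starts (a data-driven initialisation
        plus ``n_restarts - 1`` seeded Latin-hypercube points of the box).
    x0
        Optional warm start in internal vector order
        (delay, rise, amplitude, fall, undershoot_ratio, return); when given
        it is tried first, which makes repeated fits of perturbed data (e.g.
        bootstrap resamples) much cheaper.

    Returns
    -------
    FitResult
        Best-SSE solution; never raises on non-convergence (``converged`` is
        flagged instead).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size != y.size:
        raise ValueError("t and y must have the same length")
    if t.size < 20:
        raise ValueError(f"need >= 20 samples spanning the response, got {t.size}")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[k][0] for k in _PARAM_ORDER])
    hi = np.array([b[k][1] for k in _PARAM_ORDER])

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, float), lo, hi))
    if x0 is None or n_restarts > 1:
        # data-driven start: peak height and crude timings
        a0 = float(np.clip(np.max(y, initial=0.0), lo[2] + 1e-9, hi[2]))
        t_peak = float(t[np.argmax(y)]) if y.size else 1.0
        starts.append(np.clip(
            np.array([0.4, max(t_peak, 0.5), a0, 3.0, 0.1, 6.0]), lo, hi))
    n_lhs = max(n_restarts - len(starts), 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=6, seed=seed)
        for u in sampler.random(n_lhs):
            starts.append(lo + u * (hi - lo))

    best = None
    n_used = 0
    for s in starts:
        n_used += 1
        res = least_squares(_residual, s, bounds=(lo, hi), args=(t, y),
                            method="trf", xtol=1e-8, ftol=1e-8)
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res)
        # perfect fit: no point continuing
        if sse <= 1e-18 * max(1.0, float(np.sum(y ** 2))):
            break

    sse, res = best
    x = res.x
    tol = 1e-8 * (hi - lo)
    active = [name for name, xi, l, h, tl in zip(_PARAM_ORDER, x, lo, hi, tol)
              if xi - l <= tl or h - xi <= tl]
    return FitResult(
        params=_vector_to_params(x, units),
        sse=sse,
        n_restarts_used=n_used,
        converged=bool(res.success),
        bounds_active=active,
    )
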