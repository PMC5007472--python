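"""Deterministic per-trace feature extraction.

Everything the classification rules consume is computed here: the basal
(pre-onset) level, a robust noise scale, frame-to-frame jumps, the
Mann-Kendall trend statistic, plateau (equilibrium) detection, a pooled
photobleaching estimate, nonlinear curve fits, and single-cell growth rates.
All features are functions of the sampled series alone, so they are invariant
under shifting the time origin, and the basal/noise features only look at the
analysis window, so appending later frames does not change them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticParams, bateman_curve, uptake_curve

__all__ = [
    "FeatureBundle",
    "FitResult",
    "basal_level",
    "robust_noise",
    "detect_jump",
    "mk_trend",
    "mk_increasing_cutoff",
    "detect_equilibrium",
    "estimate_bleaching",
    "fit_rise",
    "cell_growth_rate",
]

# 1.4826 * MAD estimates sigma for Gaussian noise; successive differences of an
# iid series have variance 2 sigma^2, hence the extra 1/sqrt(2)
_MAD_TO_SIGMA = 1.4826


@dataclass
class FeatureBundle:
    """Per-trace features consumed by the channel/fate rules."""

    basal: float
    noise_sd: float
    jump_frames: list = field(default_factory=list)
    trend_S: int | None = None
    equilibrium_frame: int | None = None
    growth_rate: float | None = None


@dataclass
class FitResult:
    """Outcome of a kinetic curve fit; never silently unconverged."""

    params: KineticParams
    residual_norm: float
    success: bool
    message: str = ""


def _as_series(series, min_len: int, name: str = "series") -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"{name} must have at least {min_len} frames, got {x.size}")
    return x


def basal_level(series, window: int = 3) -> float:
    """Median of the first ``window`` frames (after track start / birth).

    The median makes the basal estimate robust to a single transient artifact
    frame in the window.
    """
    x = _as_series(series, window)
    return float(np.median(x[:window]))


def robust_noise(series, onset_frame: int | None = None) -> float:
    """Robust per-frame noise scale from successive differences.

    sigma_hat = 1.4826 * median(|x[i] - x[i-1]|) / sqrt(2). When an onset is
    known, only the pre-onset segment is used so the uptake ramp does not
    inflate the estimate.
    """
    x = _as_series(series, 4)
    if onset_frame is not None and onset_frame >= 4:
        x = x[:onset_frame]
    d = np.abs(np.diff(x))
    return float(_MAD_TO_SIGMA * np.median(d) / math.sqrt(2.0))


def detect_jump(series, sigma: float, k: float = 5.0, floor_au: float = 50.0) -> list[int]:
    """Frames where the series rises "drastically" between two frames.

    A jump at frame i means series[i] - series[i-1] > max(k * sigma, floor_au);
    the absolute floor guards the zero-noise limit where k*sigma would call
    every positive wiggle.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        return []
    thr = max(k * sigma, floor_au)
    return [int(i) for i in np.nonzero(np.diff(x) > thr)[0] + 1]


def mk_trend(series_window) -> int:
    """Mann-Kendall S = sum_{i<j} sign(x_j - x_i) over the window (>= 3 points)."""
    x = _as_series(series_window, 3, "trend window")
    s = np.sign(x[None, :] - x[:, None])
    return int(np.triu(s, k=1).sum())


def mk_increasing_cutoff(w: int, concordance: float = 0.8) -> int:
    """Smallest S counting as an "increasing trend" for a window of w points."""
    return math.ceil(concordance * w * (w - 1) / 2)


def detect_equilibrium(
    series,
    rel_tol: float = 0.02,
    w: int = 5,
    min_level: float | None = None,
) -> int | None:
    """Earliest frame opening a window of ``w`` frames with relative range <= rel_tol.

    The window [f, f+w) qualifies when max - min <= rel_tol * max over the
    window. ``min_level``, when given, additionally requires the window mean to
    reach that level, so that a flat pre-onset background does not count as the
    post-rise plateau. Returns None when no window qualifies.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < w:
        return None
    win = np.lib.stride_tricks.sliding_window_view(x, w)
    mx = win.max(axis=1)
    ok = (mx - win.min(axis=1)) <= rel_tol * mx
    if min_level is not None:
        ok &= win.mean(axis=1) >= min_level
    idx = np.nonzero(ok)[0]
    return int(idx[0]) if idx.size else None


def estimate_bleaching(plateau_segments) -> float:
    """Pooled per-exposure retention factor from plateau segments.

    On a stable plateau the only decay source is photobleaching, so each
    segment follows value_n = value_0 * b**n and log(value) is linear in frame
    index with slope log(b). The slope is pooled across segments by demeaning
    each segment (per-segment intercepts, common slope), which is the exact
    least-squares solution of the fixed-effects model. Returns b clipped to
    (0, 1].
    """
    segments = [np.asarray(s, dtype=float).ravel() for s in plateau_segments]
    segments = [s for s in segments if s.size >= 2]
    if not segments:
        raise ValueError("need at least one plateau segment with >= 2 frames")
    xs, ys = [], []
    for s in segments:
        if np.any(s <= 0):
            raise ValueError("plateau values must be positive for the log fit")
        n = np.arange(s.size, dtype=float)
        xs.append(n - n.mean())
        ys.append(np.log(s) - np.log(s).mean())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("segments too short to estimate a slope")
    slope = float(np.dot(x, y)) / denom
    return float(min(math.exp(slope), 1.0))


def _init_rise(t: np.ndarray, y: np.ndarray, dt_floor: float = 1.0) -> tuple[float, float, float, float]:
    """Feature-based initial guess (B, A, t0, k_in) for a rise fit.

    The half-rise interval is floored at half a frame so a rise completing
    within one frame does not seed an absurdly fast rate.
    """
    b0 = float(np.min(y))
    a0 = max(float(np.max(y)) - b0, 1e-6)
    above = np.nonzero(y > b0 + 0.05 * a0)[0]
    t0 = float(t[above[0]]) if above.size else float(t[0])
    half = np.nonzero(y > b0 + 0.5 * a0)[0]
    t_half = float(t[half[0]]) if half.size else t0 + 1.0
    k0 = math.log(2.0) / max(t_half - t0, dt_floor / 2.0, 1e-3)
    return b0, a0, t0, k0


def fit_rise(times, values, family: str = "uptake") -> FitResult:
    """Nonlinear least squares of a rise segment against ``uptake`` or ``bateman``.

    Initialization comes from trace features (basal -> B, max -> A, first rise
    -> t0, half-rise -> k_in). For the Bateman family k_in > k_out is enforced
    by swapping the rates when the optimizer crosses them (the curve is
    symmetric in the two rates up to amplitude rescaling). Non-convergence is
    reported in the result, never raised silently.
    """
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if t.size != y.size or t.size < 5:
        raise ValueError("need matching times/values with at least 5 points")
    dt_med0 = float(np.median(np.diff(t)))
    b0, a0, t0, k0 = _init_rise(t, y, dt_floor=dt_med0)
    # rates much faster than the sampling are unidentifiable (any such fit is
    # a step function); cap them at ~50 e-folds per frame interval
    dt_med = float(np.median(np.diff(t)))
    k_max = 50.0 / max(dt_med, 1e-9)

    if family == "uptake":

        def resid(p):
            B, A, tt0, k = p
            kp = KineticParams(A=max(A, 0.0), t0=tt0, k_in=max(k, 1e-9), B=max(B, 0.0))
            return uptake_curve(t, kp) - y

        starts = [[b0, a0, t0, k0]]
        # the onset is feature-detected; let the fit refine it locally only
        lower = [0.0, 0.0, max(t0 - 2.0 * dt_med, t[0] - 1.0), 1e-9]
        upper = [np.inf, np.inf, min(t0 + 2.0 * dt_med, t[-1]), k_max]
    elif family == "bateman":

        def resid(p):
            B, A, tt0, k1, k2 = p
            k_in, k_out = (k1, k2) if k1 >= k2 else (k2, k1)
            kp = KineticParams(
                A=max(A, 0.0), t0=tt0, k_in=max(k_in, 1e-9), k_out=max(k_out, 0.0), B=max(B, 0.0)
            )
            return bateman_curve(t, kp) - y

        # late-time decay slope seeds k_out
        tail = max(t.size // 4, 3)
        k2_0 = max(-np.polyfit(t[-tail:], np.log(np.maximum(y[-tail:], 1e-9)), 1)[0], 1e-4)
        starts = [
            [b0, a0 * 2.0, t0, max(f * k0, 2.0 * k2_0), k2_0]
            for f in (0.25, 1.0, 4.0)
        ]
        lower = [0.0, 0.0, max(t0 - 2.0 * dt_med, t[0] - 1.0), 1e-9, 0.0]
        upper = [np.inf, np.inf, min(t0 + 2.0 * dt_med, t[-1]), k_max, k_max]
    else:
        raise ValueError(f"unknown curve family {family!r}")

    sol = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        cand = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if sol is None or cand.cost < sol.cost:
            sol = cand
    if family == "uptake":
        B, A, tt0, k = sol.x
        params = KineticParams(A=max(A, 0.0), t0=float(tt0), k_in=max(k, 1e-9), B=max(B, 0.0))
    else:
        B, A, tt0, k1, k2 = sol.x
        k_in, k_out = (k1, k2) if k1 >= k2 else (k2, k1)
        params = KineticParams(
            A=max(A, 0.0), t0=float(tt0), k_in=max(k_in, 1e-9), k_out=max(k_out, 0.0), B=max(B, 0.0)
        )
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        success=bool(sol.success),
        message=str(sol.message),
    )


def cell_growth_rate(size_series, times_min) -> float:
    """Least-squares slope of log(size) vs time (1/min).

    Zero for a constant-size (arrested) cell, negative for a shrinking one.
    Whether a rate counts as "arrested" is a ratio test against a reference
    rate, applied by the classifier.
    """
    s = np.asarray(size_series, dtype=float).ravel()
    t = np.asarray(times_min, dtype=float).ravel()
    if s.size != t.size or s.size < 4:
        raise ValueError("need matching sizes/times with at least 4 frames")
    if np.any(s <= 0):
        raise ValueError("sizes must be positive")
    return float(np.polyfit(t, np.log(s), 1)[0])
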