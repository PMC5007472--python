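"""Closed-form fluorescence kinetics shared by the simulator and the fitting routines.

Dye uptake into a permeabilized cell is modelled as first-order influx towards a
plateau; dye loss (leakage, DNA decay, ghost-cell release) as first-order efflux.
The rise-then-decay profile of a cell that takes dye up while simultaneously
losing it is the classic one-compartment absorption/elimination (Bateman) curve.
Photobleaching is a separate, exposure-driven multiplicative loss: each imaging
exposure retains a fraction ``b`` of the current fluorophore pool.

All fluorescence values are in arbitrary units (AU); times in minutes; rates in
1/min. Curves return exactly the background ``B`` before the onset time ``t0``
(strict causality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Channel",
    "TimeGrid",
    "KineticParams",
    "BleachModel",
    "uptake_curve",
    "bateman_curve",
    "decay_curve",
    "apply_bleaching",
]

# relative rate difference below which the Bateman curve switches to its
# k_in == k_out limit form
_BATEMAN_DEGENERATE_RTOL = 1e-12


class Channel(str, Enum):
    """Fluorescence channel identity.

    ``PI`` propidium iodide (dead-cell DNA stain), ``CAL`` calcein released from
    its AM ester (metabolic activity; violet in bacteria, green in yeast),
    ``POPRO`` PO-PRO-1 (membrane-potential loss, precedes PI in apoptotic-like
    death).
    """

    PI = "PI"
    CAL = "CAL"
    POPRO = "POPRO"


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition grid: frame 0 at time 0, one frame every ``frame_interval_min``."""

    n_frames: int
    frame_interval_min: float

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (self.frame_interval_min > 0 and math.isfinite(self.frame_interval_min)):
            raise ValueError("frame_interval_min must be positive and finite")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=int)

    @property
    def times_min(self) -> np.ndarray:
        return self.frames * float(self.frame_interval_min)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the single-channel kinetic curves.

    A: plateau amplitude (AU, >= 0); t0: onset time (min); k_in: uptake rate
    (1/min, > 0); k_out: loss rate (1/min, >= 0); B: additive background (AU, >= 0).
    """

    A: float
    t0: float
    k_in: float
    k_out: float = 0.0
    B: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.A, self.t0, self.k_in, self.k_out, self.B)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite kinetic parameter in {vals}")
        if self.A < 0:
            raise ValueError("plateau amplitude A must be >= 0")
        if self.k_in <= 0:
            raise ValueError("uptake rate k_in must be > 0")
        if self.k_out < 0:
            raise ValueError("loss rate k_out must be >= 0")
        if self.B < 0:
            raise ValueError("background B must be >= 0")


@dataclass(frozen=True)
class BleachModel:
    """Per-exposure retention factor b in (0, 1]; applied once per imaged frame."""

    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.b <= 1.0):
            raise ValueError("retention factor b must lie in (0, 1]")

    @classmethod
    def from_cumulative_loss(cls, loss: float, n_frames: int) -> "BleachModel":
        """Retention per exposure giving a total fractional ``loss`` over ``n_frames``.

        E.g. a 3% cumulative loss over 120 frames gives b = 0.97**(1/120).
        """
        if not (0.0 <= loss < 1.0):
            raise ValueError("cumulative loss must lie in [0, 1)")
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        return cls((1.0 - loss) ** (1.0 / n_frames))


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    return t


def uptake_curve(t, p: KineticParams):
    """Saturating first-order uptake: B before t0, B + A(1 - exp(-k_in (t - t0))) after.

    Non-decreasing in t and bounded by B + A; reaches the plateau to within
    1e-9 relative once k_in*(t - t0) >= 25.
    """
    t = _check_times(t)
    tau = np.maximum(t - p.t0, 0.0)
    out = p.B + p.A * (-np.expm1(-p.k_in * tau))
    return out if out.ndim else float(out)


def bateman_curve(t, p: KineticParams):
    """One-compartment absorption/elimination (rise then decay).

    B + A * k_in/(k_in - k_out) * (exp(-k_out tau) - exp(-k_in tau)) for
    tau = t - t0 >= 0, with the continuous limit B + A k_in tau exp(-k_in tau)
    as k_out -> k_in. The peak sits at tau* = ln(k_in/k_out)/(k_in - k_out).
    """
    t = _check_times(t)
    tau = np.maximum(t - p.t0, 0.0)
    if abs(p.k_in - p.k_out) <= _BATEMAN_DEGENERATE_RTOL * p.k_in:
        out = p.B + p.A * p.k_in * tau * np.exp(-p.k_in * tau)
    else:
        ratio = p.k_in / (p.k_in - p.k_out)
        out = p.B + p.A * ratio * (np.exp(-p.k_out * tau) - np.exp(-p.k_in * tau))
    return out if out.ndim else float(out)


def decay_curve(t, p: KineticParams):
    """First-order loss from a loaded state: B + A exp(-k_out (t - t0)) for t >= t0.

    Monotone non-increasing; tends to B. Before t0 the cell is still fully
    loaded (returns B + A).
    """
    t = _check_times(t)
    tau = np.maximum(t - p.t0, 0.0)
    out = p.B + p.A * np.exp(-p.k_out * tau)
    return out if out.ndim else float(out)


def apply_bleaching(value, n_exposures: int, m: BleachModel):
    """Fluorescence remaining after ``n_exposures`` imaging exposures: value * b**n.

    Multiplicative and order-independent, so exposures compose additively:
    applying n then k exposures equals applying n + k.
    """
    if n_exposures < 0:
        raise ValueError("exposure count must be >= 0")
    value = np.asarray(value, dtype=float)
    out = value * m.b ** int(n_exposures)
    return out if out.ndim else float(out)
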