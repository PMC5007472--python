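"""Rule-based per-channel dye calls and the trajectory-level fate state machine.

A channel turns positive at the earliest frame supported by either kind of
evidence: a drastic frame-to-frame jump, or a sustained rise above the basal
level that shows an increasing Mann-Kendall trend and eventually settles into
an equilibrium plateau. Cells already stained when observation starts (e.g.
pre-culture deaths present at seeding) are positive from frame 0.

The fate of a trajectory is then decided by a fixed precedence of rules over
the channel onsets, lysis detection, growth arrest and lineage events:
lysis without prior PI, PI then lysis, staged PO-PRO-1->PI onsets
(apoptotic-like), simultaneous onsets (necrotic-like; plain dead when no
PO-PRO-1 channel was recorded), PO-PRO-1 recovery followed by division
(resuscitation), then the viable states split by growth arrest and calcein
level. All rules operate on background-subtracted series, so calls are
invariant under a constant offset applied to background and values alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .features import (
    basal_level,
    detect_equilibrium,
    detect_jump,
    mk_increasing_cutoff,
    mk_trend,
    robust_noise,
)
from .kinetics import Channel
from .simulate import FateLabel

__all__ = [
    "Thresholds",
    "CellState",
    "ChannelCall",
    "FateCall",
    "call_channel",
    "call_cal_level",
    "detect_lysis",
    "classify_fate",
    "classify_polarity",
    "DEAD_CLASS",
    "VIABLE_CLASS",
]

#: label classes used by the two-pole (segmented cell) comparison
DEAD_CLASS = frozenset({FateLabel.DEAD, FateLabel.NECROTIC_LIKE, FateLabel.DEAD_THEN_LYSED})
VIABLE_CLASS = frozenset({FateLabel.TOLERANT, FateLabel.ARRESTED_VIABLE, FateLabel.GROWING})


@dataclass(frozen=True)
class Thresholds:
    """All tunable decision constants of the classifier.

    rel_rise is the fractional rise above basal that counts as staining (5%);
    the absolute floors (jump_floor_au, rise_floor_au) guard the zero-noise
    and zero-basal limits where a purely relative rule would call every
    wiggle. apoptosis_lag_frames is the smallest PO-PRO-1 -> PI onset lag that
    distinguishes staged (apoptotic-like) from simultaneous (necrotic-like)
    double staining.
    """

    rel_rise: float = 0.05
    sustain_frames: int = 3
    jump_k: float = 5.0
    jump_floor_au: float = 50.0
    rise_floor_au: float = 25.0
    initial_pos_floor_au: float = 150.0
    initial_pos_k: float = 10.0
    cal_high_ratio: float = 2.0
    cal_abs_high_au: float = 400.0
    apoptosis_lag_frames: int = 2
    background_margin_k: float = 3.0
    lysis_floor_au: float = 10.0
    lysis_consecutive: int = 2
    lysis_lookback: int = 3
    lysis_peak_frac: float = 0.5
    lysis_peak_window: int = 10
    lysis_stain_factor: float = 2.0
    recovery_drop_frac: float = 0.5
    arrest_frac: float = 0.1
    min_reference_rate: float = 1e-3
    basal_window: int = 3
    trend_window: int = 5
    trend_concordance: float = 0.8
    eq_window: int = 5
    eq_rel_tol: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.rel_rise < 1.0):
            raise ValueError("rel_rise must lie in (0, 1)")
        if self.apoptosis_lag_frames < 1:
            raise ValueError("apoptosis_lag_frames must be >= 1")
        for name in ("sustain_frames", "jump_k", "cal_high_ratio", "background_margin_k",
                     "recovery_drop_frac", "arrest_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CellState(str, Enum):
    """Per-frame physiological state used by the state sequences."""

    ALIVE = "ALIVE"
    MORIBUND = "MORIBUND"  # PO-PRO-1 positive, PI negative
    DEAD = "DEAD"
    LYSED = "LYSED"


# transitions the state machine may take
_ALLOWED_TRANSITIONS = {
    (CellState.ALIVE, CellState.MORIBUND),
    (CellState.ALIVE, CellState.DEAD),
    (CellState.ALIVE, CellState.LYSED),
    (CellState.MORIBUND, CellState.DEAD),
    (CellState.MORIBUND, CellState.ALIVE),
    (CellState.DEAD, CellState.LYSED),
}


@dataclass
class ChannelCall:
    """Per-channel dye positivity with its onset frame and evidence."""

    channel: Channel
    onset_frame: int | None
    basal: float
    noise_sd: float
    evidence: str | None = None  # jump | sustained_rise | initial
    equilibrium_frame: int | None = None
    equilibrium_value: float | None = None

    @property
    def positive(self) -> bool:
        return self.onset_frame is not None

    def status(self, frame: int) -> str:
        if self.onset_frame is None or frame < self.onset_frame:
            return "neg"
        return "pos"


@dataclass
class FateCall:
    """Trajectory-level outcome: final label plus the per-frame state sequence."""

    final_label: FateLabel
    state_sequence: list[tuple[int, CellState]]
    onset_pi: int | None = None
    onset_popro: int | None = None
    lysis_frame: int | None = None
    recovery_frame: int | None = None
    cal_level: str | None = None
    arrested: bool | None = None

    def __post_init__(self) -> None:
        for (f0, s0), (f1, s1) in zip(self.state_sequence, self.state_sequence[1:]):
            if f1 <= f0:
                raise ValueError("state_sequence frames must strictly increase")
            if (s0, s1) not in _ALLOWED_TRANSITIONS:
                raise ValueError(f"disallowed state transition {s0.value} -> {s1.value}")
        if (
            self.final_label is FateLabel.APOPTOTIC_LIKE
            and self.onset_pi is not None
            and self.onset_popro is not None
            and self.onset_pi < self.onset_popro
        ):
            raise ValueError("apoptotic-like call with PI onset before PO-PRO-1 onset")

    def state_at(self, frame: int) -> CellState:
        state = self.state_sequence[0][1]
        for f, s in self.state_sequence:
            if frame >= f:
                state = s
            else:
                break
        return state


def _rise_threshold(basal: float, thresholds: Thresholds) -> float:
    return basal + max(thresholds.rel_rise * max(basal, 0.0), thresholds.rise_floor_au)


def call_channel(
    series,
    thresholds: Thresholds = Thresholds(),
    channel: Channel = Channel.PI,
    sigma: float | None = None,
) -> ChannelCall:
    """Dye-positivity call for one background-subtracted series.

    Positive from the earliest frame with either (a) a jump exceeding
    max(jump_k * sigma, jump_floor_au) between two frames, or (b) a run of
    sustain_frames consecutive frames above the basal rise threshold whose
    local Mann-Kendall trend is increasing and that is eventually followed by
    an equilibrium plateau at or above that threshold. A series already
    elevated at track start is positive from frame 0 (evidence "initial").
    The noise scale is re-estimated on the pre-onset segment once an onset is
    found, which can only sharpen the jump threshold.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < max(4, thresholds.basal_window):
        raise ValueError("series too short to call")
    th = thresholds

    def _call(sig: float) -> tuple[int | None, str | None]:
        basal = basal_level(x, th.basal_window)
        candidates: list[tuple[int, str]] = []
        if basal > max(th.initial_pos_k * sig, th.initial_pos_floor_au):
            candidates.append((0, "initial"))
        jumps = detect_jump(x, sig, th.jump_k, th.jump_floor_au)
        if jumps:
            candidates.append((jumps[0], "jump"))
        t_rise = _rise_threshold(basal, th)
        above = x > t_rise
        run = np.convolve(above.astype(int), np.ones(th.sustain_frames, dtype=int), mode="valid")
        for f in np.nonzero(run == th.sustain_frames)[0]:
            f = int(f)
            if f == 0:
                continue  # already covered by the initial-positivity rule
            w = min(th.trend_window, x.size - f)
            if w < 3:
                break
            if mk_trend(x[f : f + w]) < mk_increasing_cutoff(w, th.trend_concordance):
                continue
            eq = detect_equilibrium(x[f:], th.eq_rel_tol, th.eq_window, min_level=t_rise)
            if eq is None:
                continue
            candidates.append((f, "sustained_rise"))
            break
        if not candidates:
            return None, None
        onset = min(f for f, _ in candidates)
        # earliest-evidence rule; on ties a jump outranks a sustained rise
        order = {"jump": 0, "initial": 1, "sustained_rise": 2}
        evidence = sorted((f, order[e], e) for f, e in candidates)[0][2]
        return onset, evidence

    sig0 = sigma if sigma is not None else robust_noise(x)
    onset, evidence = _call(sig0)
    if sigma is None and onset is not None and onset >= 4:
        onset2, evidence2 = _call(robust_noise(x, onset_frame=onset))
        if onset2 is not None:
            onset, evidence = onset2, evidence2

    basal = basal_level(x, th.basal_window)
    eq_frame = eq_value = None
    if onset is not None:
        eq = detect_equilibrium(
            x[onset:], th.eq_rel_tol, th.eq_window, min_level=_rise_threshold(basal, th)
        )
        if eq is None and evidence in ("jump", "initial"):
            eq = detect_equilibrium(x[onset:], th.eq_rel_tol, th.eq_window)
        if eq is not None:
            eq_frame = onset + int(eq)
            eq_value = float(np.mean(x[eq_frame : eq_frame + th.eq_window]))
    return ChannelCall(
        channel=channel,
        onset_frame=onset,
        basal=float(basal),
        noise_sd=float(sig0),
        evidence=evidence,
        equilibrium_frame=eq_frame,
        equilibrium_value=eq_value,
    )


def call_cal_level(
    series,
    growing_reference_values,
    thresholds: Thresholds = Thresholds(),
    noise_sd: float = 0.0,
    warn: list | None = None,
) -> str:
    """Calcein level of one cell: neg / pos (moderate, CAL+) / high (CAL++).

    The evaluation window is the trailing eq_window frames; "high" means its
    mean reaches cal_high_ratio times the median of co-cultivated growing
    reference cells at comparable frames. With no reference available the
    call falls back to an absolute threshold (and says so via ``warn``).
    """
    x = np.asarray(series, dtype=float).ravel()
    th = thresholds
    m = float(np.mean(x[-th.eq_window :]))
    if m <= th.background_margin_k * max(noise_sd, th.lysis_floor_au / th.background_margin_k):
        return "neg"
    ref = np.asarray(growing_reference_values, dtype=float).ravel()
    if ref.size == 0:
        if warn is not None:
            warn.append("empty calcein reference; falling back to absolute threshold")
        return "high" if m >= th.cal_abs_high_au else "pos"
    ref_med = float(np.median(ref))
    if ref_med <= 0:
        return "high" if m >= th.cal_abs_high_au else "pos"
    return "high" if m >= th.cal_high_ratio * ref_med else "pos"


def detect_lysis(
    series_by_channel: dict[Channel, np.ndarray],
    background_sd: dict[Channel, float],
    thresholds: Thresholds = Thresholds(),
) -> int | None:
    """Ghost-cell (lysis) detection on background-subtracted series.

    Lysis is the earliest frame from which every recorded channel stays within
    the background envelope (background_margin_k * noise, with an absolute
    floor) for at least lysis_consecutive frames, provided (i) at least one
    channel previously exceeded that envelope (otherwise the cell was simply
    never stained), and (ii) the loss was abrupt: some previously stained
    channel still held at least lysis_peak_frac of its running peak within
    lysis_lookback frames before the collapse. The abruptness guard separates
    ghost-cell collapse from gradual, recovery-like fluorescence loss.
    """
    th = thresholds
    chans = list(series_by_channel)
    if not chans:
        return None
    arrs = [np.asarray(series_by_channel[c], dtype=float).ravel() for c in chans]
    n = arrs[0].size
    env = [
        max(th.background_margin_k * background_sd.get(c, 0.0), th.lysis_floor_au)
        for c in chans
    ]
    within = np.ones(n, dtype=bool)
    for a, e in zip(arrs, env):
        within &= a <= e
    # "previously stained" means clearly above the envelope, not a single
    # noise excursion just past it
    stain = [th.lysis_stain_factor * e for e in env]
    ever_above = [bool(np.any(a > s)) for a, s in zip(arrs, stain)]
    if not any(ever_above):
        return None
    k = th.lysis_consecutive
    run = np.convolve(within.astype(int), np.ones(k, dtype=int), mode="valid")
    for f in np.nonzero(run == k)[0]:
        f = int(f)
        if f == 0:
            continue  # never stained up to here
        ok = False
        for a, s, above in zip(arrs, stain, ever_above):
            if not above:
                continue
            # recent peak: dye partitioned to daughters at divisions must not
            # make an earlier, higher level the abruptness reference
            peak = float(np.max(a[max(f - th.lysis_peak_window, 0) : f]))
            if peak <= s:
                continue
            lo = max(f - th.lysis_lookback, 0)
            if float(np.max(a[lo:f])) >= th.lysis_peak_frac * peak:
                ok = True
                break
        if ok:
            return f
    return None


def classify_fate(
    calls: dict[Channel, ChannelCall],
    growth_rate: float | None,
    lineage_events: list[int],
    thresholds: Thresholds = Thresholds(),
    lysis_frame: int | None = None,
    series: dict[Channel, np.ndarray] | None = None,
    reference_rate: float | None = None,
    cal_reference_values=None,
    birth_frame: int = 0,
    b_hat: float = 1.0,
) -> FateCall:
    """Deterministic fate state machine over the channel calls.

    Precedence: (1) lysis with no prior PI onset -> LYSED_DIRECT; (2) PI then
    lysis -> DEAD_THEN_LYSED; (3) PO-PRO-1 leading PI by at least
    apoptosis_lag_frames -> APOPTOTIC_LIKE; (4) PI with simultaneous/absent
    PO-PRO-1 -> NECROTIC_LIKE, reported as DEAD when no PO-PRO-1 channel was
    recorded; (5) PO-PRO-1 that fades below recovery_drop_frac of its peak
    (beyond the bleaching extrapolation b_hat) followed by a division ->
    RESUSCITATED; (6)/(7) arrested cells split by calcein level into TOLERANT
    vs ARRESTED_VIABLE; (8) otherwise GROWING. Onset frames are absolute
    (``birth_frame`` locates the trace on the movie grid).
    """
    th = thresholds
    series = series or {}
    pi = calls.get(Channel.PI)
    popro = calls.get(Channel.POPRO)
    cal = calls.get(Channel.CAL)

    def _abs(local: int | None) -> int | None:
        return None if local is None else birth_frame + local

    onset_pi = _abs(pi.onset_frame if pi else None)
    onset_popro = _abs(popro.onset_frame if popro else None)
    lysis_abs = _abs(lysis_frame)

    # growth evidence: a rate comparable to the reference, or an actual division
    ref = max(reference_rate or 0.0, th.min_reference_rate)
    rate_ok = growth_rate is not None and growth_rate >= th.arrest_frac * ref
    divided = bool(lineage_events)
    arrested = not (rate_ok or divided)

    cal_level = None
    if cal is not None and Channel.CAL in series:
        cal_level = call_cal_level(
            series[Channel.CAL],
            cal_reference_values if cal_reference_values is not None else [],
            th,
            noise_sd=cal.noise_sd,
        )

    recovery_abs = None
    if popro is not None and popro.onset_frame is not None and Channel.POPRO in series:
        x = np.asarray(series[Channel.POPRO], dtype=float).ravel()
        seg = x[popro.onset_frame :]
        ipk = int(np.argmax(seg))
        peak = float(seg[ipk])
        post = seg[ipk + 1 :]
        if post.size:
            drops = np.nonzero(
                post < th.recovery_drop_frac * peak * (b_hat ** np.arange(1, post.size + 1))
            )[0]
            if drops.size:
                recovery_abs = birth_frame + popro.onset_frame + ipk + 1 + int(drops[0])

    seq: list[tuple[int, CellState]] = [(birth_frame, CellState.ALIVE)]

    def _push(frame: int | None, state: CellState) -> None:
        if frame is None:
            return
        last_f, last_s = seq[-1]
        if state is last_s:
            return
        if frame <= last_f:
            seq[-1] = (last_f, state)  # events collapsing onto one frame
        else:
            seq.append((frame, state))

    # precedence
    if lysis_abs is not None and (onset_pi is None or onset_pi >= lysis_abs):
        label = FateLabel.LYSED_DIRECT
        _push(lysis_abs, CellState.LYSED)
        onset_pi = None  # a "PI onset" at/after collapse is not a staining event
    elif lysis_abs is not None and onset_pi is not None:
        label = FateLabel.DEAD_THEN_LYSED
        if onset_popro is not None and onset_popro < onset_pi:
            _push(onset_popro, CellState.MORIBUND)
        _push(onset_pi, CellState.DEAD)
        _push(lysis_abs, CellState.LYSED)
    elif (
        onset_pi is not None
        and onset_popro is not None
        and onset_pi - onset_popro >= th.apoptosis_lag_frames
    ):
        label = FateLabel.APOPTOTIC_LIKE
        _push(onset_popro, CellState.MORIBUND)
        _push(onset_pi, CellState.DEAD)
    elif onset_pi is not None:
        label = FateLabel.NECROTIC_LIKE if popro is not None else FateLabel.DEAD
        _push(onset_pi, CellState.DEAD)
    elif (
        onset_popro is not None
        and recovery_abs is not None
        and any(ev > recovery_abs for ev in lineage_events)
    ):
        label = FateLabel.RESUSCITATED
        _push(onset_popro, CellState.MORIBUND)
        _push(recovery_abs, CellState.ALIVE)
    elif onset_popro is not None:
        # PO-PRO-1 positive without PI or recovery: dying (necrotic-like entry)
        label = FateLabel.NECROTIC_LIKE
        _push(onset_popro, CellState.MORIBUND)
    elif arrested and cal_level == "high":
        label = FateLabel.TOLERANT
    elif arrested:
        label = FateLabel.ARRESTED_VIABLE
    else:
        label = FateLabel.GROWING

    return FateCall(
        final_label=label,
        state_sequence=seq,
        onset_pi=onset_pi,
        onset_popro=onset_popro,
        lysis_frame=lysis_abs,
        recovery_frame=recovery_abs if label is FateLabel.RESUSCITATED else None,
        cal_level=cal_level,
        arrested=arrested,
    )


def classify_polarity(pole_a: FateCall, pole_b: FateCall) -> str:
    """"segmented" when the two poles carry discordant dead/viable states."""
    la, lb = pole_a.final_label, pole_b.final_label
    if la == lb:
        return "uniform"
    discordant = (la in DEAD_CLASS and lb in VIABLE_CLASS) or (
        lb in DEAD_CLASS and la in VIABLE_CLASS
    )
    return "segmented" if discordant else "uniform"
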