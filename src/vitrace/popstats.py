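"""Population-level summaries and evaluation against simulator ground truth.

Summaries are frame-resolved: state occupancy (alive / moribund / dead /
lysed) over the cells present at each frame, the live fraction, and colony
mean +/- SD fluorescence per channel. Experiment-level quantities cover final
fate-label fractions, PI-positive frequencies at seeding and at the end, and
the population growth rate (log-linear slope of total live biomass), which is
reported normalized to an untreated reference run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CellState, FateCall, FateLabel
from .kinetics import Channel
from .pipeline import ClassificationResult
from .simulate import CellTrace, GroundTruth

__all__ = [
    "PopulationSummary",
    "EvaluationReport",
    "summarize",
    "live_fraction_curve",
    "normalized_growth_rate",
    "pi_positive_frequency",
    "evaluate",
]


@dataclass
class PopulationSummary:
    """Per-frame occupancy/fluorescence table plus experiment-level fractions."""

    per_frame: pd.DataFrame  # frame, time_min, n_present, counts/fractions, live_fraction, channel mean/sd
    final_label_fractions: dict[FateLabel, float]
    n_cells: int
    n_ancestors: int

    def live_fraction(self) -> np.ndarray:
        return self.per_frame["live_fraction"].to_numpy()


@dataclass
class EvaluationReport:
    """Confusion matrix and summary scores of calls vs ground truth."""

    confusion: pd.DataFrame  # rows: true label, columns: called label
    accuracy: float
    recall: dict[str, float]
    precision: dict[str, float]
    n: int

    def min_recall(self) -> float:
        return min(self.recall.values())


_STATE_LIVE = {CellState.ALIVE: True, CellState.MORIBUND: False,
               CellState.DEAD: False, CellState.LYSED: False}


def _cell_state_at(calls: list[FateCall], frame: int) -> CellState:
    """State of a cell at a frame; for bipolar cells the more alive pole rules
    (a cell with one surviving pole is not wholly dead)."""
    states = [fc.state_at(frame) for fc in calls]
    for s in (CellState.ALIVE, CellState.MORIBUND, CellState.DEAD, CellState.LYSED):
        if s in states:
            return s
    return states[0]


def summarize(traces: list[CellTrace], result: ClassificationResult) -> PopulationSummary:
    """Frame-resolved population summary from traces plus their fate calls."""
    if not traces:
        raise ValueError("no traces to summarize")
    by_cell: dict[str, list[CellTrace]] = {}
    for tr in traces:
        if (tr.cell_id, tr.compartment) not in result.fate_calls:
            raise ValueError(f"missing fate call for {(tr.cell_id, tr.compartment)}")
        by_cell.setdefault(tr.cell_id, []).append(tr)

    n_frames = max(int(tr.frames[-1]) for tr in traces) + 1
    frames = np.arange(n_frames)
    dt = float(traces[0].times_min[1] - traces[0].times_min[0]) if traces[0].frames.size > 1 else 0.0

    state_counts = {s: np.zeros(n_frames, dtype=int) for s in CellState}
    present = np.zeros(n_frames, dtype=int)
    chan_sum: dict[Channel, np.ndarray] = {}
    chan_sumsq: dict[Channel, np.ndarray] = {}
    chan_n: dict[Channel, np.ndarray] = {}

    for cid, trs in by_cell.items():
        calls = [result.fate_calls[(tr.cell_id, tr.compartment)] for tr in trs]
        birth = min(tr.birth_frame for tr in trs)
        last = max(int(tr.frames[-1]) for tr in trs)
        present[birth : last + 1] += 1
        for f in range(birth, last + 1):
            state_counts[_cell_state_at(calls, f)][f] += 1
        for tr in trs:
            for ch, v in tr.values.items():
                if ch not in chan_sum:
                    chan_sum[ch] = np.zeros(n_frames)
                    chan_sumsq[ch] = np.zeros(n_frames)
                    chan_n[ch] = np.zeros(n_frames, dtype=int)
                sl = slice(tr.birth_frame, tr.birth_frame + v.size)
                chan_sum[ch][sl] += v
                chan_sumsq[ch][sl] += v * v
                chan_n[ch][sl] += 1

    data: dict[str, np.ndarray] = {
        "frame": frames,
        "time_min": frames * dt,
        "n_present": present,
    }
    safe = np.maximum(present, 1)
    for s in CellState:
        data[f"n_{s.value.lower()}"] = state_counts[s]
        data[f"frac_{s.value.lower()}"] = state_counts[s] / safe
    data["live_fraction"] = state_counts[CellState.ALIVE] / safe
    for ch in chan_sum:
        n = np.maximum(chan_n[ch], 1)
        mean = chan_sum[ch] / n
        var = np.maximum(chan_sumsq[ch] / n - mean**2, 0.0)
        data[f"mean_{ch.value}"] = mean
        data[f"sd_{ch.value}"] = np.sqrt(var)

    final_counts: dict[FateLabel, int] = {}
    for cid in by_cell:
        lab = result.cell_labels[cid]
        final_counts[lab] = final_counts.get(lab, 0) + 1
    n_cells = len(by_cell)
    fractions = {lab: c / n_cells for lab, c in final_counts.items()}
    n_ancestors = sum(1 for trs in by_cell.values() if trs[0].parent_id is None)

    return PopulationSummary(
        per_frame=pd.DataFrame(data),
        final_label_fractions=fractions,
        n_cells=n_cells,
        n_ancestors=n_ancestors,
    )


def live_fraction_curve(summary: PopulationSummary) -> np.ndarray:
    """Per-frame fraction of present cells whose state is alive."""
    return summary.live_fraction()


def _total_live_size(traces: list[CellTrace], result: ClassificationResult,
                     n_frames: int) -> np.ndarray:
    total = np.zeros(n_frames)
    for tr in traces:
        fc = result.fate_calls[(tr.cell_id, tr.compartment)]
        for i, f in enumerate(tr.frames):
            if _STATE_LIVE[fc.state_at(int(f))]:
                total[int(f)] += tr.size[i]
    return total


def growth_rate_of(traces: list[CellTrace], result: ClassificationResult,
                   window: tuple[int, int] | None = None) -> float:
    """Population growth rate: log-linear slope (1/min) of total live biomass."""
    n_frames = max(int(tr.frames[-1]) for tr in traces) + 1
    dt = float(traces[0].times_min[1] - traces[0].times_min[0])
    total = _total_live_size(traces, result, n_frames)
    lo, hi = window if window else (0, n_frames)
    t = np.arange(lo, hi) * dt
    y = total[lo:hi]
    keep = y > 0
    if keep.sum() < 2:
        return float("nan")
    return float(np.polyfit(t[keep], np.log(y[keep]), 1)[0])


def normalized_growth_rate(
    treated_traces: list[CellTrace],
    treated_result: ClassificationResult,
    reference_traces: list[CellTrace],
    reference_result: ClassificationResult,
    window: tuple[int, int] | None = None,
) -> float:
    """Ratio of population growth rates, treated over untreated reference.

    Flagged (NaN) when the reference rate is not positive.
    """
    r_t = growth_rate_of(treated_traces, treated_result, window)
    r_r = growth_rate_of(reference_traces, reference_result, window)
    if not np.isfinite(r_r) or r_r <= 0:
        return float("nan")
    return r_t / r_r


def pi_positive_frequency(
    traces: list[CellTrace],
    result: ClassificationResult,
    at: str = "end",
) -> float:
    """Percentage of cells in a PI-positive state at seeding or at the end.

    PI-positive means the cell's state at the queried frame is dead (not yet
    lysed). At seeding only ancestors are present, so the frequency is over
    ancestors by construction.
    """
    if at not in ("seeding", "end"):
        raise ValueError("at must be 'seeding' or 'end'")
    by_cell: dict[str, list] = {}
    births: dict[str, int] = {}
    lasts: dict[str, int] = {}
    for tr in traces:
        fc = result.fate_calls[(tr.cell_id, tr.compartment)]
        by_cell.setdefault(tr.cell_id, []).append(fc)
        births[tr.cell_id] = min(births.get(tr.cell_id, tr.birth_frame), tr.birth_frame)
        lasts[tr.cell_id] = max(lasts.get(tr.cell_id, 0), int(tr.frames[-1]))
    n_frames = max(lasts.values()) + 1
    frame = 0 if at == "seeding" else n_frames - 1
    present = [cid for cid in by_cell if births[cid] <= frame <= lasts[cid]]
    if not present:
        raise ValueError("no cells present at the requested frame")
    n_pos = sum(
        1 for cid in present if _cell_state_at(by_cell[cid], frame) is CellState.DEAD
    )
    return 100.0 * n_pos / len(present)


def evaluate(result: ClassificationResult, truth: GroundTruth) -> EvaluationReport:
    """Confusion matrix, accuracy, and per-class recall/precision of the
    per-cell final labels against the simulator's ground truth."""
    called = result.cell_labels
    true = truth.cell_labels
    common = sorted(set(called) & set(true))
    if not common:
        raise ValueError("no overlap between calls and ground truth")
    if set(called) != set(true):
        raise ValueError("calls and ground truth cover different cells")
    labels = [l.value for l in FateLabel]
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for cid in common:
        conf.loc[true[cid].value, called[cid].value] += 1
    present = [l for l in labels if conf.loc[l].sum() > 0 or conf[l].sum() > 0]
    conf = conf.loc[present, present]
    n = len(common)
    acc = float(np.trace(conf.to_numpy())) / n
    recall = {}
    precision = {}
    for l in present:
        row = conf.loc[l].sum()
        col = conf[l].sum()
        if row > 0:
            recall[l] = float(conf.loc[l, l]) / row
        if col > 0:
            precision[l] = float(conf.loc[l, l]) / col
    return EvaluationReport(confusion=conf, accuracy=acc, recall=recall,
                            precision=precision, n=n)
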