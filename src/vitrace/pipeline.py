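"""End-to-end classification of a trace set.

Ties the pieces together for a whole experiment: estimates the per-channel
background from the population, background-subtracts every trace, extracts
features, makes the channel calls, detects lysis, determines growth arrest
against a population reference rate, resolves calcein levels against
co-cultivated growing cells, runs the fate state machine per trace, and
finally merges pole calls into per-cell labels (segmented/bipolar cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    CellState,
    ChannelCall,
    FateCall,
    FateLabel,
    Thresholds,
    call_channel,
    classify_fate,
    classify_polarity,
    detect_lysis,
)
from .features import basal_level, cell_growth_rate, robust_noise
from .kinetics import Channel
from .simulate import CellTrace

__all__ = ["ClassificationResult", "classify_traces"]

# severity order used to pick a representative label for uniform bipolar cells
_SEVERITY = [
    FateLabel.LYSED_DIRECT,
    FateLabel.DEAD_THEN_LYSED,
    FateLabel.NECROTIC_LIKE,
    FateLabel.APOPTOTIC_LIKE,
    FateLabel.DEAD,
    FateLabel.RESUSCITATED,
    FateLabel.TOLERANT,
    FateLabel.ARRESTED_VIABLE,
    FateLabel.GROWING,
]


@dataclass
class ClassificationResult:
    """Per-trace fate calls plus per-cell labels and run-level context."""

    fate_calls: dict[tuple[str, str], FateCall]
    channel_calls: dict[tuple[str, str], dict[Channel, ChannelCall]]
    cell_labels: dict[str, FateLabel]
    polarity: dict[str, str]
    background: dict[Channel, float]
    reference_rate: float
    thresholds: Thresholds
    warnings: list[str] = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for (cid, comp), fc in sorted(self.fate_calls.items()):
            rows.append(
                {
                    "cell_id": cid,
                    "compartment": comp,
                    "final_label": fc.final_label.value,
                    "cell_label": self.cell_labels[cid].value,
                    "onset_pi": fc.onset_pi,
                    "onset_popro": fc.onset_popro,
                    "lysis_frame": fc.lysis_frame,
                    "recovery_frame": fc.recovery_frame,
                    "cal_level": fc.cal_level,
                    "arrested": fc.arrested,
                    "state_sequence": ";".join(f"{f}:{s.value}" for f, s in fc.state_sequence),
                }
            )
        return pd.DataFrame(rows)


def _estimate_background(traces: list[CellTrace], thresholds: Thresholds) -> dict[Channel, float]:
    """Per-channel population background from the first frame of ancestor
    traces: at acquisition start no dye has accumulated yet, so the median
    first-frame value across seeded cells estimates the additive background
    (robust to a few cells already stained at seeding). Falls back to a
    per-trace low quantile when no ancestors are present."""
    firsts: dict[Channel, list[float]] = {}
    for tr in traces:
        if tr.parent_id is not None or tr.birth_frame != 0:
            continue
        for ch, v in tr.values.items():
            firsts.setdefault(ch, []).append(float(v[0]))
    out = {ch: float(np.median(vals)) for ch, vals in firsts.items() if vals}
    proxies: dict[Channel, list[float]] = {}
    for tr in traces:
        for ch, v in tr.values.items():
            if ch in out or v.size < thresholds.basal_window:
                continue
            lo = min(basal_level(v, thresholds.basal_window), float(np.percentile(v, 10)))
            proxies.setdefault(ch, []).append(lo)
    for ch, vals in proxies.items():
        out[ch] = float(np.median(vals))
    return out


def classify_traces(
    traces: list[CellTrace],
    thresholds: Thresholds | None = None,
    reference_rate: float | None = None,
) -> ClassificationResult:
    """Classify every trace of an experiment and merge pole calls per cell."""
    th = thresholds or Thresholds()
    if not traces:
        raise ValueError("no traces to classify")
    warnings: list[str] = []
    background = _estimate_background(traces, th)

    # lineage events: a cell's divisions are its daughters' birth frames
    divisions: dict[str, list[int]] = {}
    for tr in traces:
        if tr.parent_id is not None:
            divisions.setdefault(tr.parent_id, []).append(tr.birth_frame)
    for v in divisions.values():
        v.sort()

    # pass 1: subtraction, features, growth rates
    sub: dict[tuple[str, str], dict[Channel, np.ndarray]] = {}
    rates: dict[tuple[str, str], float | None] = {}
    for tr in traces:
        key = (tr.cell_id, tr.compartment)
        sub[key] = {ch: v - background.get(ch, 0.0) for ch, v in tr.values.items()}
        n = tr.size.size
        if n >= 8:
            w = max(n // 2, 4)
            rates[key] = cell_growth_rate(tr.size[-w:], tr.times_min[-w:])
        elif n >= 4:
            rates[key] = cell_growth_rate(tr.size, tr.times_min)
        else:
            rates[key] = None

    if reference_rate is None:
        valid = [r for r in rates.values() if r is not None]
        reference_rate = float(np.quantile(valid, 0.8)) if valid else 0.0
    reference_rate = max(reference_rate, th.min_reference_rate)

    # pass 2: channel calls and lysis
    channel_calls: dict[tuple[str, str], dict[Channel, ChannelCall]] = {}
    lysis_frames: dict[tuple[str, str], int | None] = {}
    for tr in traces:
        key = (tr.cell_id, tr.compartment)
        calls: dict[Channel, ChannelCall] = {}
        bg_sd: dict[Channel, float] = {}
        for ch, x in sub[key].items():
            if x.size < max(4, th.basal_window):
                continue
            call = call_channel(x, th, channel=ch)
            calls[ch] = call
            bg_sd[ch] = robust_noise(x, onset_frame=call.onset_frame)
        channel_calls[key] = calls
        lysis_frames[key] = (
            detect_lysis({ch: sub[key][ch] for ch in calls}, bg_sd, th) if calls else None
        )

    # growing reference cells for the calcein-level ratio
    ref_values: list[np.ndarray] = []
    for tr in traces:
        key = (tr.cell_id, tr.compartment)
        calls = channel_calls.get(key, {})
        if Channel.CAL not in calls:
            continue
        pi_on = calls.get(Channel.PI) and calls[Channel.PI].positive
        pop_on = calls.get(Channel.POPRO) and calls[Channel.POPRO].positive
        rate = rates[key]
        growing = (rate is not None and rate >= th.arrest_frac * reference_rate) or bool(
            divisions.get(tr.cell_id)
        )
        if not pi_on and not pop_on and lysis_frames[key] is None and growing:
            ref_values.append(sub[key][Channel.CAL][-th.eq_window :])
    cal_reference = np.concatenate(ref_values) if ref_values else np.array([])
    if cal_reference.size == 0:
        warnings.append("no growing calcein reference cells; absolute CAL threshold in use")

    # pass 3: fate calls
    fate_calls: dict[tuple[str, str], FateCall] = {}
    for tr in traces:
        key = (tr.cell_id, tr.compartment)
        calls = channel_calls.get(key, {})
        if not calls:
            # trace too short to analyse: treat as an unremarkable growing cell
            fate_calls[key] = FateCall(
                final_label=FateLabel.GROWING,
                state_sequence=[(tr.birth_frame, CellState.ALIVE)],
            )
            continue
        fate_calls[key] = classify_fate(
            calls,
            growth_rate=rates[key],
            lineage_events=divisions.get(tr.cell_id, []),
            thresholds=th,
            lysis_frame=lysis_frames[key],
            series=sub[key],
            reference_rate=reference_rate,
            cal_reference_values=cal_reference,
            birth_frame=tr.birth_frame,
        )

    # per-cell labels: merge poles
    by_cell: dict[str, dict[str, FateCall]] = {}
    for (cid, comp), fc in fate_calls.items():
        by_cell.setdefault(cid, {})[comp] = fc
    cell_labels: dict[str, FateLabel] = {}
    polarity: dict[str, str] = {}
    for cid, comps in by_cell.items():
        if "pole_A" in comps and "pole_B" in comps:
            pol = classify_polarity(comps["pole_A"], comps["pole_B"])
            polarity[cid] = pol
            if pol == "segmented":
                cell_labels[cid] = FateLabel.SEGMENTED_BIPOLAR
            else:
                labels = {comps["pole_A"].final_label, comps["pole_B"].final_label}
                cell_labels[cid] = next(l for l in _SEVERITY if l in labels)
        else:
            fc = comps.get("whole") or next(iter(comps.values()))
            cell_labels[cid] = fc.final_label
            polarity[cid] = "uniform"

    return ClassificationResult(
        fate_calls=fate_calls,
        channel_calls=channel_calls,
        cell_labels=cell_labels,
        polarity=polarity,
        background=background,
        reference_rate=reference_rate,
        thresholds=th,
        warnings=warnings,
    )
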