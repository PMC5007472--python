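"""File formats: long-format trace CSV, ground-truth JSON, report CSV,
summary TSV, and run configuration (YAML/JSON).

The trace table is this package's interchange format: one row per
(cell, compartment, frame, channel) with columns cell_id, parent_id,
compartment, frame, time_min, channel, value_au, size_au. UTF-8, comma
separator, '.' decimals, NA as empty string; frames are 0-based and must be
contiguous per trace. Real-image feature tables (from external segmentation/
tracking tools) plug in by being exported to this schema; no proprietary
microscope formats are read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import Thresholds
from .kinetics import BleachModel, Channel
from .pipeline import ClassificationResult
from .popstats import EvaluationReport, PopulationSummary
from .simulate import AcquisitionConfig, CellTrace, FateLabel, GroundTruth, PopulationConfig

__all__ = [
    "TRACE_COLUMNS",
    "SCHEMA_VERSION",
    "RunConfig",
    "write_traces",
    "read_traces",
    "write_truth",
    "read_truth",
    "write_report",
    "write_summary",
    "write_evaluation",
    "load_run_config",
]

SCHEMA_VERSION = "vitrace-v1"
TRACE_COLUMNS = [
    "cell_id",
    "parent_id",
    "compartment",
    "frame",
    "time_min",
    "channel",
    "value_au",
    "size_au",
]
_COMPARTMENTS = {"whole", "pole_A", "pole_B"}


class TraceSchemaError(ValueError):
    """Trace table violates the schema; message names column/row/cell."""


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for ch, v in tr.values.items():
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": tr.cell_id,
                        "parent_id": tr.parent_id if tr.parent_id is not None else "",
                        "compartment": tr.compartment,
                        "frame": tr.frames,
                        "time_min": tr.times_min,
                        "channel": ch.value,
                        "value_au": v,
                        "size_au": tr.size,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def write_traces(traces: list[CellTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[CellTrace]:
    """Read and validate a trace CSV; schema violations name column and row."""
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str, "compartment": str,
                                  "channel": str}, keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"missing column(s): {', '.join(missing)}")
    return frame_to_traces(df)


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    bad = ~df["compartment"].isin(_COMPARTMENTS)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise TraceSchemaError(f"invalid compartment at row {row + 2}: {df['compartment'].iloc[row]!r}")
    bad = ~df["channel"].isin([c.value for c in Channel])
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise TraceSchemaError(f"invalid channel at row {row + 2}: {df['channel'].iloc[row]!r}")
    if (df["value_au"].to_numpy() < 0).any():
        row = int(np.nonzero(df["value_au"].to_numpy() < 0)[0][0])
        raise TraceSchemaError(f"negative value_au at row {row + 2}")
    dup = df.duplicated(subset=["cell_id", "compartment", "frame", "channel"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0])
        raise TraceSchemaError(f"duplicate (cell_id, compartment, frame, channel) at row {row + 2}")

    traces = []
    for (cid, comp), grp in df.groupby(["cell_id", "compartment"], sort=True):
        channels = sorted(grp["channel"].unique())
        frames = np.sort(grp["frame"].unique())
        if not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
            raise TraceSchemaError(f"non-contiguous frames for cell {cid!r} ({comp})")
        values: dict[Channel, np.ndarray] = {}
        size = None
        times = None
        for ch in channels:
            g = grp[grp["channel"] == ch].sort_values("frame")
            if not np.array_equal(g["frame"].to_numpy(), frames):
                raise TraceSchemaError(f"channel {ch} frame set differs for cell {cid!r}")
            values[Channel(ch)] = g["value_au"].to_numpy(dtype=float)
            size = g["size_au"].to_numpy(dtype=float)
            times = g["time_min"].to_numpy(dtype=float)
        parent = grp["parent_id"].iloc[0]
        traces.append(
            CellTrace(
                cell_id=str(cid),
                parent_id=str(parent) if parent not in ("", None) else None,
                compartment=str(comp),
                frames=frames.astype(int),
                times_min=times,
                values=values,
                size=size,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# ground truth JSON


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "schema": SCHEMA_VERSION,
        "cell_labels": {cid: lab.value for cid, lab in truth.cell_labels.items()},
        "division_frames": truth.division_frames,
        "programs": {
            f"{cid}|{comp}": {
                "label": prog.label.value,
                "t_arrest": prog.t_arrest,
                "t_popro": prog.t_popro,
                "t_pi": prog.t_pi,
                "t_lysis": prog.t_lysis,
                "t_recover": prog.t_recover,
                "division_times": list(prog.division_times),
                "partition": prog.partition,
                "growth_rate": prog.growth_rate,
                "birth_time": prog.birth_time,
            }
            for (cid, comp), prog in truth.programs.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> GroundTruth:
    """Read the evaluation-relevant part of a truth JSON (labels, divisions).

    Kinetic profiles are generative detail and are not round-tripped.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported truth schema: {payload.get('schema')!r}")
    return GroundTruth(
        programs={},
        cell_labels={cid: FateLabel(v) for cid, v in payload["cell_labels"].items()},
        division_frames={cid: list(map(int, v)) for cid, v in payload.get("division_frames", {}).items()},
    )


# ---------------------------------------------------------------------------
# report / summary / evaluation writers


def write_report(result: ClassificationResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} classification report\n")
        result.report_frame().to_csv(fh, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary(summary: PopulationSummary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} population summary\n")
        summary.per_frame.to_csv(fh, sep="\t", index=False)


def write_evaluation(report: EvaluationReport, path) -> None:
    payload = {
        "schema": SCHEMA_VERSION,
        "n": report.n,
        "accuracy": report.accuracy,
        "recall": report.recall,
        "precision": report.precision,
        "confusion": {
            true: {col: int(report.confusion.loc[true, col]) for col in report.confusion.columns}
            for true in report.confusion.index
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated CLI run configuration (unknown keys rejected)."""

    acquisition: AcquisitionConfig
    population: PopulationConfig
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "."


def _build(cls, data: dict, name: str):
    import dataclasses

    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {name} key(s): {', '.join(sorted(unknown))}")
    return cls(**data)


def load_run_config(path) -> RunConfig:
    """Load a YAML/JSON run config and validate every section."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(data) - {"acquisition", "population", "thresholds", "seed", "outdir", "species"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    acq_data = dict(data.get("acquisition", {}))
    if "bleach" in acq_data and acq_data["bleach"] is not None:
        acq_data["bleach"] = {
            Channel(k): BleachModel(float(v)) for k, v in acq_data["bleach"].items()
        }
    if "species" in data:
        from .simulate import preset_acquisition

        base = preset_acquisition(data["species"])
        acq = _build(
            AcquisitionConfig,
            {**{"frame_interval_min": base.frame_interval_min, "n_frames": base.n_frames}, **acq_data},
            "acquisition",
        )
    else:
        acq = _build(AcquisitionConfig, acq_data, "acquisition")

    pop_data = dict(data.get("population", {}))
    if "composition" in pop_data:
        pop_data["composition"] = {
            FateLabel(k): float(v) for k, v in pop_data["composition"].items()
        }
    pop = _build(PopulationConfig, pop_data, "population")
    thr = _build(Thresholds, dict(data.get("thresholds", {})), "thresholds")
    return RunConfig(
        acquisition=acq,
        population=pop,
        thresholds=thr,
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", ".")),
    )
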