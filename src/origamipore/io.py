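"""Readers and writers for traces, ground truth, event tables, fits and yields.

Trace dialects
--------------
``csv``
    Two-column headered text, ``time_s,current_pA``; the sampling rate is
    recovered from the time column.
``binary``
    Raw little-endian float32 current samples plus a ``<stem>.json`` sidecar
    holding ``sampling_rate``, ``units`` and any generator metadata.
``vendor``
    Reserved for amplifier vendor formats behind the same contract; not
    implemented here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import EVENT_COLUMNS, DetectionConfig, EventTable
from .ecs import ECSComponent, ECSFitResult, YieldReport
from .gel import GelLaneTable
from .simulate import GROUND_TRUTH_COLUMNS, GeneratorConfig
from .trace import TraceRecording


# ---------------------------------------------------------------- traces

def write_trace_csv(trace: TraceRecording, path) -> None:
    frame = pd.DataFrame({"time_s": trace.times, "current_pA": trace.current})
    frame.to_csv(path, index=False)


def write_trace_binary(trace: TraceRecording, path) -> None:
    """float32 payload at ``path`` plus a JSON sidecar at ``path + '.json'``."""
    path = Path(path)
    trace.current.astype("<f4").tofile(path)
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "lowpass_cutoff": trace.lowpass_cutoff,
        "units": "pA",
        "dtype": "<f4",
        "label": trace.label,
        "metadata": trace.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path, format: str = "csv") -> TraceRecording:
    """Read a trace in the declared dialect (``csv`` or ``binary``)."""
    path = Path(path)
    if format == "csv":
        return _read_trace_csv(path)
    if format == "binary":
        return _read_trace_binary(path)
    if format == "vendor":
        raise NotImplementedError(
            "vendor electrophysiology formats are not supported in this build; "
            "convert to the csv or binary dialect (same TraceRecording contract)"
        )
    raise ValueError(f"unknown trace format {format!r}")


def _read_trace_csv(path: Path) -> TraceRecording:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "current_pA"):
        if col not in frame.columns:
            raise ValueError(f"trace CSV {path} missing required column {col!r}")
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
        raise ValueError("trace CSV time column is not uniformly sampled")
    return TraceRecording(
        current=frame["current_pA"].to_numpy(dtype=float),
        sampling_rate=1.0 / float(np.median(dt)),
        label=path.stem,
    )


def _read_trace_binary(path: Path) -> TraceRecording:
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"binary trace {path} has no JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "sampling_rate" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} missing 'sampling_rate'")
    if sidecar.get("units", "pA") != "pA":
        raise ValueError(f"sidecar declares units {sidecar.get('units')!r}; expected 'pA'")
    payload = path.read_bytes()
    if len(payload) % 4:
        raise ValueError(f"binary trace {path} payload truncated (not a whole float32 count)")
    current = np.frombuffer(payload, dtype="<f4").astype(float)
    return TraceRecording(
        current=current,
        sampling_rate=float(sidecar["sampling_rate"]),
        lowpass_cutoff=sidecar.get("lowpass_cutoff"),
        label=sidecar.get("label", path.stem),
        metadata=sidecar.get("metadata", {}),
    )


# ------------------------------------------------------ tables and results

def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth[GROUND_TRUTH_COLUMNS].to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ground-truth CSV missing columns: {missing}")
    return frame


def write_event_table(table: EventTable, path) -> None:
    """Event CSV with columns sample_label, start_s, end_s, dwell_ms,
    peak_max_pA, ecs, local_baseline_pA."""
    frame = table.events[EVENT_COLUMNS].copy()
    frame.insert(0, "sample_label", table.sample_label)
    frame.to_csv(path, index=False)


def read_event_table(path, trace_duration: float = 0.0) -> EventTable:
    frame = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event CSV missing columns: {missing}")
    label = str(frame["sample_label"].iloc[0]) if len(frame) and "sample_label" in frame else ""
    return EventTable(frame.drop(columns=["sample_label"], errors="ignore"), label, trace_duration)


def write_fit_result(fit: ECSFitResult, path) -> None:
    doc = {
        "sample_label": fit.sample_label,
        "residual_ss": fit.residual_ss,
        "bin_edges": fit.bin_edges.tolist(),
        "bin_counts": fit.bin_counts.tolist(),
        "components": [
            {
                "label": c.label,
                "mean": c.mean,
                "sd": c.sd,
                "amplitude": c.amplitude,
                "fixed_mean": c.fixed_mean,
            }
            for c in fit.components
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit_result(path) -> ECSFitResult:
    doc = json.loads(Path(path).read_text())
    return ECSFitResult(
        components=[ECSComponent(**c) for c in doc["components"]],
        bin_edges=np.asarray(doc["bin_edges"], dtype=float),
        bin_counts=np.asarray(doc["bin_counts"], dtype=int),
        residual_ss=float(doc["residual_ss"]),
        sample_label=doc.get("sample_label", ""),
    )


def write_yield_reports(reports, path) -> None:
    rows = [
        {"sample_label": r.sample_label, "component": lab, "percent": pct,
         "is_target": lab == r.target_label}
        for r in reports
        for lab, pct in r.per_component
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gel_lanes(path) -> list[GelLaneTable]:
    """Lane CSV with columns lane_label, component, intensity, n_monomers."""
    frame = pd.read_csv(path)
    required = ["lane_label", "component", "intensity", "n_monomers"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"gel lane CSV missing columns: {missing}")
    lanes = []
    for label, grp in frame.groupby("lane_label", sort=False):
        bands = list(zip(grp["component"], grp["intensity"], grp["n_monomers"]))
        lanes.append(GelLaneTable(label, bands))
    return lanes


# --------------------------------------------------------------- configs

def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_generator_config(data: dict) -> GeneratorConfig:
    return _from_dict(GeneratorConfig, data)


def load_detection_config(data: dict) -> DetectionConfig:
    return _from_dict(DetectionConfig, data)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
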