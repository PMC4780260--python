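"""CSV/JSON readers and writers for the session data model.

Dialects
--------
* trajectory CSV: ``time_s,x,y`` or ``time_s,compartment``
* spike CSV: ``unit_id,time_s`` (many units per file)
* event CSV: ``onset_s[,duration_s]``
* geometry JSON: ``{"maze_kind": ..., "compartments": [{"label", "xmin",
  "xmax", "ymin", "ymax"}], "arm_type_map": {...}}``
* sweep CSV: one column per sweep, with the acquisition metadata
  supplied alongside
* physiology CSV: ``time_s,value,error_flag``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MazeGeometry, Rect, SpikeTrain, Trajectory
from .events import EventSeries
from .evoked import PhysioTrace, Sweep

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_events_csv",
    "read_geometry_json",
    "write_geometry_json",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "read_physio_csv",
    "write_physio_csv",
]


def read_trajectory_csv(
    path, session_duration: float | None = None
) -> Trajectory:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a time_s column")
    times = df["time_s"].to_numpy(dtype=float)
    duration = (
        float(times[-1]) + (float(np.median(np.diff(times))) if times.size > 1 else 0.0)
        if session_duration is None
        else session_duration
    )
    if "compartment" in df.columns:
        return Trajectory(
            sample_times=times,
            session_duration=duration,
            labels=df["compartment"].to_numpy(dtype=object),
        )
    if {"x", "y"}.issubset(df.columns):
        return Trajectory(
            sample_times=times,
            session_duration=duration,
            positions=df[["x", "y"]].to_numpy(dtype=float),
        )
    raise ValueError(
        f"{path}: expected columns time_s,x,y or time_s,compartment"
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    data: dict = {"time_s": traj.sample_times}
    if traj.labels is not None:
        data["compartment"] = traj.labels
    elif traj.positions is not None:
        data["x"] = traj.positions[:, 0]
        data["y"] = traj.positions[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_spikes_csv(
    path, session_duration: float | None = None
) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    missing = {"unit_id", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(
                unit_id=str(unit_id),
                spike_times=np.sort(grp["time_s"].to_numpy(dtype=float)),
                session_duration=session_duration,
            )
        )
    return trains


def write_spikes_csv(trains: list[SpikeTrain], path) -> None:
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "time_s": t.spike_times})
        for t in trains
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    out.to_csv(path, index=False)


def read_events_csv(path, kind: str, duration: float | None = None) -> EventSeries:
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise ValueError(f"{path}: expected an onset_s column")
    if duration is None:
        if "duration_s" not in df.columns:
            raise ValueError(
                f"{path}: need a duration_s column or an explicit duration"
            )
        durs = df["duration_s"].to_numpy(dtype=float)
        if np.unique(durs).size != 1:
            raise ValueError(f"{path}: per-event durations must be uniform")
        duration = float(durs[0])
    return EventSeries(kind, df["onset_s"].to_numpy(dtype=float), duration)


def read_geometry_json(path) -> MazeGeometry:
    spec = json.loads(Path(path).read_text())
    comps = {
        c["label"]: Rect(c["xmin"], c["xmax"], c["ymin"], c["ymax"])
        for c in spec["compartments"]
    }
    return MazeGeometry(spec["maze_kind"], comps, spec["arm_type_map"])


def write_geometry_json(geom: MazeGeometry, path) -> None:
    spec = {
        "maze_kind": geom.maze_kind,
        "compartments": [
            {
                "label": lab,
                "xmin": r.xmin,
                "xmax": r.xmax,
                "ymin": r.ymin,
                "ymax": r.ymax,
            }
            for lab, r in geom.compartments.items()
        ],
        "arm_type_map": dict(geom.arm_type_map),
    }
    Path(path).write_text(json.dumps(spec, indent=2))


def read_sweeps_csv(
    path,
    sampling_rate: float = 10_000.0,
    pulse_onset: float = 0.1,
    baseline_window: tuple[float, float] | None = None,
) -> list[Sweep]:
    df = pd.read_csv(path)
    if baseline_window is None:
        baseline_window = (0.0, pulse_onset)
    return [
        Sweep(
            samples=df[col].to_numpy(dtype=float),
            sampling_rate=sampling_rate,
            pulse_onset=pulse_onset,
            baseline_window=baseline_window,
        )
        for col in df.columns
    ]


def write_sweeps_csv(sweeps: list[Sweep], path) -> None:
    pd.DataFrame(
        {f"sweep{i}": s.samples for i, s in enumerate(sweeps)}
    ).to_csv(path, index=False)


def read_physio_csv(path, kind: str) -> PhysioTrace:
    df = pd.read_csv(path)
    missing = {"value", "error_flag"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return PhysioTrace(
        values=df["value"].to_numpy(dtype=float),
        error_flags=df["error_flag"].to_numpy(dtype=bool),
        kind=kind,
    )


def write_physio_csv(trace: PhysioTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": np.arange(trace.values.size, dtype=float),
            "value": trace.values,
            "error_flag": trace.error_flags.astype(int),
        }
    ).to_csv(path, index=False)
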