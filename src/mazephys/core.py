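"""Session data model shared by every analysis stage.

A recording session couples an animal trajectory (position samples at a
nominal 30 Hz, assigned to named maze compartments) with one or more
single-unit spike trains.  All firing-rate bookkeeping — occupancy per
compartment, spike attribution, per-compartment rates — lives here so
the scoring and event modules can stay purely statistical.

Conventions
-----------
* Times are seconds from session start; sample intervals are half-open
  ``[t_i, t_{i+1})``, so each spike is attributed to the nearest
  *preceding* trajectory sample (zero-order hold).
* Compartments are axis-aligned rectangles, half-open on their upper
  edges so that abutting regions never both contain a point.
* A position contained by no region is labelled :data:`OUTSIDE`; such
  samples are kept in the trajectory but their spikes enter no
  per-compartment count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OUTSIDE",
    "EPM_ARM_LABELS",
    "CLOSED_ARM_LABELS",
    "OPEN_ARM_LABELS",
    "Rect",
    "MazeGeometry",
    "Trajectory",
    "SpikeTrain",
    "CompartmentRates",
    "assign_compartment",
    "label_trajectory",
    "compartment_rates",
    "pooled_rate",
]

OUTSIDE = "outside"

CLOSED_ARM_LABELS = ("closed_left", "closed_right")
OPEN_ARM_LABELS = ("open_up", "open_down")
EPM_ARM_LABELS = CLOSED_ARM_LABELS + OPEN_ARM_LABELS

ARM_TYPES = ("closed", "open", "other")


class GeometryError(ValueError):
    """Invalid maze geometry (overlap, missing arm types, ...)."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open on the max edges."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise GeometryError(f"degenerate rectangle {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.xmin <= x < self.xmax and self.ymin <= y < self.ymax

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.xmin < other.xmax
            and other.xmin < self.xmax
            and self.ymin < other.ymax
            and other.ymin < self.ymax
        )


@dataclass(frozen=True)
class MazeGeometry:
    """Named planar compartments plus an arm-type map.

    ``arm_type_map`` sends every compartment label to one of
    ``{"closed", "open", "other"}``.  For a plus maze the four arms must
    be exactly two closed and two open; the hub is ``center`` with arm
    type ``other``.
    """

    maze_kind: str  # "EPM" | "LDT" | "OFT" | "HOME"
    compartments: Mapping[str, Rect]
    arm_type_map: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = list(self.compartments)
        for lab in labels:
            if lab not in self.arm_type_map:
                raise GeometryError(f"no arm type for compartment {lab!r}")
            if self.arm_type_map[lab] not in ARM_TYPES:
                raise GeometryError(
                    f"arm type {self.arm_type_map[lab]!r} for {lab!r} "
                    f"not in {ARM_TYPES}"
                )
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if self.compartments[a].overlaps(self.compartments[b]):
                    raise GeometryError(f"compartments {a!r} and {b!r} overlap")
        if self.maze_kind == "EPM":
            closed = [l for l, t in self.arm_type_map.items() if t == "closed"]
            open_ = [l for l, t in self.arm_type_map.items() if t == "open"]
            if sorted(closed) != sorted(CLOSED_ARM_LABELS) or sorted(
                open_
            ) != sorted(OPEN_ARM_LABELS):
                raise GeometryError(
                    "EPM geometry needs exactly the four arm labels "
                    f"{EPM_ARM_LABELS}"
                )

    @classmethod
    def standard_epm(
        cls, arm_length: float = 30.0, arm_width: float = 6.0
    ) -> "MazeGeometry":
        """Plus maze centred at the origin: left/right closed, up/down open."""
        h = arm_width / 2.0
        L = arm_length
        comps = {
            "center": Rect(-h, h, -h, h),
            "closed_left": Rect(-h - L, -h, -h, h),
            "closed_right": Rect(h, h + L, -h, h),
            "open_up": Rect(-h, h, h, h + L),
            "open_down": Rect(-h, h, -h - L, -h),
        }
        arm_types = {
            "center": "other",
            "closed_left": "closed",
            "closed_right": "closed",
            "open_up": "open",
            "open_down": "open",
        }
        return cls("EPM", comps, arm_types)

    @classmethod
    def standard_ldt(
        cls, box_length: float = 40.0, box_width: float = 20.0
    ) -> "MazeGeometry":
        """Two-compartment light/dark box; the lit half is anxiogenic."""
        half = box_length / 2.0
        comps = {
            "light": Rect(0.0, half, 0.0, box_width),
            "dark": Rect(-half, 0.0, 0.0, box_width),
        }
        return cls("LDT", comps, {"light": "other", "dark": "other"})

    def labels_of_type(self, arm_type: str) -> tuple[str, ...]:
        return tuple(
            l for l, t in self.arm_type_map.items() if t == arm_type
        )


def assign_compartment(
    position: Sequence[float], geometry: MazeGeometry
) -> str:
    """Label of the unique compartment containing ``position``.

    Returns :data:`OUTSIDE` when no compartment contains the point.
    Overlap at the query point is a configuration error (the geometry
    validator should have caught it, but rounding in hand-built
    geometries can slip through).
    """
    x, y = float(position[0]), float(position[1])
    hits = [
        lab for lab, r in geometry.compartments.items() if r.contains(x, y)
    ]
    if len(hits) > 1:
        raise GeometryError(f"point ({x}, {y}) falls in {hits}")
    return hits[0] if hits else OUTSIDE


@dataclass
class Trajectory:
    """Regularly sampled animal positions, optionally pre-labelled.

    Either ``positions`` (N x 2 planar coordinates, same units as the
    geometry) or ``labels`` (per-sample compartment names) must be
    present; when both are given the labels take precedence.
    """

    sample_times: np.ndarray
    session_duration: float
    positions: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.sample_times.size == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        t0, t1 = self.sample_times[0], self.sample_times[-1]
        if t0 < 0 or t1 > self.session_duration:
            raise ValueError(
                f"samples [{t0}, {t1}] outside [0, {self.session_duration}]"
            )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.sample_times.size, 2):
                raise ValueError("positions must be (n_samples, 2)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.sample_times.shape:
                raise ValueError("labels must match sample count")
        if self.positions is None and self.labels is None:
            raise ValueError("trajectory needs positions or labels")

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)

    @property
    def sample_interval(self) -> float:
        """Nominal sampling interval (median inter-sample gap)."""
        if self.n_samples < 2:
            raise ValueError("sample interval undefined for one sample")
        return float(np.median(np.diff(self.sample_times)))

    def time_slice(self, t_start: float, t_stop: float) -> "Trajectory":
        """Sub-trajectory with samples in ``[t_start, t_stop)``."""
        m = (self.sample_times >= t_start) & (self.sample_times < t_stop)
        if not m.any():
            raise ValueError(f"no samples in [{t_start}, {t_stop})")
        return Trajectory(
            sample_times=self.sample_times[m],
            session_duration=self.session_duration,
            positions=None if self.positions is None else self.positions[m],
            labels=None if self.labels is None else self.labels[m],
        )


def label_trajectory(
    traj: Trajectory, geometry: MazeGeometry
) -> Trajectory:
    """Attach a per-sample compartment label to a positional trajectory.

    Samples outside every compartment are kept and labelled
    :data:`OUTSIDE` — they still consume occupancy time in the session
    but contribute to no compartment.
    """
    if traj.positions is None:
        raise ValueError("label_trajectory needs positions")
    labels = np.array(
        [assign_compartment(p, geometry) for p in traj.positions],
        dtype=object,
    )
    return Trajectory(
        sample_times=traj.sample_times,
        session_duration=traj.session_duration,
        positions=traj.positions,
        labels=labels,
    )


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one unit within one session."""

    unit_id: str
    spike_times: np.ndarray
    session_duration: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if self.session_duration is not None and self.spike_times.size:
            if (
                self.spike_times[0] < 0
                or self.spike_times[-1] > self.session_duration
            ):
                raise ValueError("spikes outside [0, session_duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def time_slice(self, t_start: float, t_stop: float) -> "SpikeTrain":
        m = (self.spike_times >= t_start) & (self.spike_times < t_stop)
        return SpikeTrain(
            self.unit_id, self.spike_times[m], self.session_duration
        )


@dataclass
class CompartmentRates:
    """Occupancy, spike count and rate per compartment for one unit.

    ``rates[label]`` is NaN where the compartment was never occupied —
    an undefined rate is flagged, never silently zero.  The session mean
    rate uses the full session duration (centre time and out-of-maze
    gaps included), matching the whole-maze normalisation that the
    fold-rate statistic downstream expects.
    """

    unit_id: str
    occupancy: dict[str, float]
    spike_counts: dict[str, int]
    rates: dict[str, float]
    mean_rate: float
    n_spikes: int
    session_duration: float

    def occupied(self, label: str) -> bool:
        return self.occupancy.get(label, 0.0) > 0.0


def compartment_rates(
    spikes: SpikeTrain,
    traj: Trajectory,
    sample_interval: float | None = None,
) -> CompartmentRates:
    """Per-compartment firing rates for one unit.

    Occupancy per label is (number of samples so labelled) x (sampling
    interval).  Each spike is attributed to the label of the
    nearest-preceding trajectory sample; spikes before the first sample,
    and spikes whose sample is labelled :data:`OUTSIDE`, enter no
    compartment count.  The mean rate is ``n_spikes / session_duration``.
    """
    if traj.labels is None:
        raise ValueError("compartment_rates needs a labelled trajectory")
    dt = traj.sample_interval if sample_interval is None else sample_interval
    labels = np.asarray(traj.labels)
    uniq = [l for l in dict.fromkeys(labels.tolist()) if l != OUTSIDE]

    occupancy = {
        lab: float(np.count_nonzero(labels == lab)) * dt for lab in uniq
    }
    counts = {lab: 0 for lab in uniq}

    if spikes.n_spikes:
        idx = np.searchsorted(traj.sample_times, spikes.spike_times, "right") - 1
        valid = idx >= 0  # spikes before the first sample are unattributed
        spike_labels = labels[idx[valid]]
        for lab in uniq:
            counts[lab] = int(np.count_nonzero(spike_labels == lab))

    rates = {
        lab: (counts[lab] / occupancy[lab]) if occupancy[lab] > 0 else np.nan
        for lab in uniq
    }
    mean_rate = spikes.n_spikes / traj.session_duration
    return CompartmentRates(
        unit_id=spikes.unit_id,
        occupancy=occupancy,
        spike_counts=counts,
        rates=rates,
        mean_rate=mean_rate,
        n_spikes=spikes.n_spikes,
        session_duration=traj.session_duration,
    )


def pooled_rate(cr: CompartmentRates, labels: Sequence[str]) -> float:
    """Rate pooled over several compartments: total spikes / total time.

    NaN when none of the compartments was occupied.
    """
    occ = sum(cr.occupancy.get(l, 0.0) for l in labels)
    if occ <= 0:
        return float("nan")
    n = sum(cr.spike_counts.get(l, 0) for l in labels)
    return n / occ
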