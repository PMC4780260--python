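"""Deterministic signal-decision rules.

Three small detectors share this module:

* postsynaptic-current responder detection on voltage-clamp sweeps —
  baseline-subtract and average 5-15 traces, then flag a responder when
  the peak deflection within 50 ms of the light pulse exceeds 5 s.d. of
  the averaged trace's baseline noise;
* multiunit event detection on filtered extracellular traces —
  threshold crossings at 3 s.d. from baseline with a 1-ms dead time;
* pulse-oximetry quality control — drop error-flagged samples, smooth
  with a trailing moving average (10 samples respiratory, 5 heart),
  and include a session only when at least 30% of its samples are
  error-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Sweep",
    "EvokedResult",
    "PhysioTrace",
    "PhysioQC",
    "detect_evoked_response",
    "detect_multiunit_events",
    "qc_physiology",
]

RESPONSE_WINDOW = 0.050      # s after the pulse searched for a peak
RESPONDER_SD = 5.0           # responder iff |peak| > 5 x baseline s.d.
MULTIUNIT_SD = 3.0           # threshold for multiunit event crossings
DEAD_TIME = 0.001            # s, refractory guard between multiunit events
QC_MIN_ERROR_FREE = 0.30     # session inclusion floor
SMOOTH_WINDOW = {"respiratory": 10, "heart": 5}


@dataclass
class Sweep:
    """One voltage-clamp trace at a fixed sampling rate (nominally 10 kHz)."""

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    pulse_onset: float = 0.1           # s
    baseline_window: tuple[float, float] = (0.0, 0.1)  # s, before the pulse

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.pulse_onset):
            raise ValueError("baseline window must precede the pulse")
        if int(b1 * self.sampling_rate) - int(b0 * self.sampling_rate) < 1:
            raise ValueError("baseline window contains no samples")

    def _idx(self, t: float) -> int:
        return int(round(t * self.sampling_rate))


@dataclass
class EvokedResult:
    mean_trace: np.ndarray
    baseline_sd: float
    peak_amplitude: float     # signed, from the baseline-subtracted average
    peak_latency_ms: float    # ms after pulse onset
    is_responder: bool
    n_sweeps: int


def detect_evoked_response(
    sweeps: list[Sweep],
    response_window: float = RESPONSE_WINDOW,
    threshold_sd: float = RESPONDER_SD,
) -> EvokedResult:
    """Responder decision from a set of repeated sweeps.

    Each sweep is baseline-subtracted (mean over its baseline window)
    and the sweeps averaged.  The peak is the largest-magnitude
    deflection of the averaged trace in ``(pulse, pulse + 50 ms]``,
    searched over both polarities since both outward and inward
    currents occur.  Noise s.d. is taken from the averaged trace's
    baseline window; the cell is a responder iff |peak| exceeds
    ``threshold_sd`` times that s.d.
    """
    if len(sweeps) < 2:
        raise ValueError("need at least 2 sweeps")
    if len(sweeps) > 50:
        raise ValueError("more than 50 sweeps; check the input")
    if not 5 <= len(sweeps) <= 15:
        warnings.warn(
            f"{len(sweeps)} sweeps; 5-15 is the intended range",
            stacklevel=2,
        )
    first = sweeps[0]
    n = first.samples.size
    for s in sweeps[1:]:
        if s.samples.size != n:
            raise ValueError("sweeps have mismatched lengths")
        if (
            s.sampling_rate != first.sampling_rate
            or s.pulse_onset != first.pulse_onset
            or s.baseline_window != first.baseline_window
        ):
            raise ValueError("sweeps have mismatched acquisition metadata")

    b0 = first._idx(first.baseline_window[0])
    b1 = first._idx(first.baseline_window[1])
    stack = np.stack([s.samples for s in sweeps])
    stack = stack - stack[:, b0:b1].mean(axis=1, keepdims=True)
    mean_trace = stack.mean(axis=0)

    baseline_sd = float(mean_trace[b0:b1].std(ddof=1))
    p0 = first._idx(first.pulse_onset)
    p1 = min(first._idx(first.pulse_onset + response_window), n - 1)
    seg = mean_trace[p0 + 1 : p1 + 1]  # (pulse, pulse + window]
    if seg.size == 0:
        raise ValueError("response window contains no samples")
    k = int(np.argmax(np.abs(seg)))
    peak = float(seg[k])
    latency_ms = (k + 1) / first.sampling_rate * 1000.0
    responder = bool(abs(peak) > threshold_sd * baseline_sd)
    return EvokedResult(
        mean_trace=mean_trace,
        baseline_sd=baseline_sd,
        peak_amplitude=peak,
        peak_latency_ms=latency_ms,
        is_responder=responder,
        n_sweeps=len(sweeps),
    )


def detect_multiunit_events(
    trace: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
    threshold_sd: float = MULTIUNIT_SD,
    polarity: str = "both",
    dead_time: float = DEAD_TIME,
) -> np.ndarray:
    """Times (s) of threshold crossings on a filtered trace.

    Events are crossings of baseline mean +/- ``threshold_sd`` s.d.
    (``polarity``: "positive", "negative" or "both"), with successive
    events closer than ``dead_time`` collapsed onto the first.
    """
    trace = np.asarray(trace, dtype=float)
    b0 = int(round(baseline_window[0] * sampling_rate))
    b1 = int(round(baseline_window[1] * sampling_rate))
    base = trace[b0:b1]
    if base.size < 2:
        raise ValueError("baseline window too short")
    mu, sd = base.mean(), base.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance baseline")

    if polarity == "positive":
        above = trace > mu + threshold_sd * sd
    elif polarity == "negative":
        above = trace < mu - threshold_sd * sd
    elif polarity == "both":
        above = np.abs(trace - mu) > threshold_sd * sd
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        crossings = np.union1d(crossings, [0])
    times = crossings / sampling_rate

    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= dead_time:
            kept.append(float(t))
    return np.asarray(kept)


@dataclass
class PhysioTrace:
    """1-Hz pulse-oximetry stream with per-sample motion-error flags."""

    values: np.ndarray       # breaths/min or beats/min
    error_flags: np.ndarray  # True where the sample is a motion artefact
    kind: str                # "respiratory" | "heart"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.error_flags = np.asarray(self.error_flags, dtype=bool)
        if self.values.shape != self.error_flags.shape:
            raise ValueError("values and error flags must align")
        if self.kind not in SMOOTH_WINDOW:
            raise ValueError(f"kind must be one of {list(SMOOTH_WINDOW)}")

    @property
    def error_free_fraction(self) -> float:
        if self.values.size == 0:
            return 0.0
        return float(np.count_nonzero(~self.error_flags) / self.values.size)


@dataclass
class PhysioQC:
    included: bool
    error_free_fraction: float
    clean_values: np.ndarray   # error-flagged samples removed
    smoothed: np.ndarray       # trailing moving average of clean_values
    full_window: np.ndarray    # False where the trailing window was short
    window: int


def qc_physiology(
    trace: PhysioTrace,
    min_error_free: float = QC_MIN_ERROR_FREE,
) -> PhysioQC:
    """Smooth an oximetry stream and decide session inclusion.

    Error-flagged samples are removed before smoothing.  Smoothing is a
    trailing moving average over 10 samples (respiratory) or 5 (heart);
    leading samples with an incomplete window are passed through
    unsmoothed and flagged in ``full_window``.  The session is included
    iff its error-free fraction is at least ``min_error_free``.
    """
    frac = trace.error_free_fraction
    included = frac >= min_error_free
    clean = trace.values[~trace.error_flags]
    w = SMOOTH_WINDOW[trace.kind]
    if clean.size == 0:
        return PhysioQC(
            included=False,
            error_free_fraction=frac,
            clean_values=clean,
            smoothed=np.empty(0),
            full_window=np.empty(0, dtype=bool),
            window=w,
        )
    smoothed = clean.astype(float).copy()
    full = np.zeros(clean.size, dtype=bool)
    if clean.size >= w:
        csum = np.concatenate([[0.0], np.cumsum(clean)])
        smoothed[w - 1 :] = (csum[w:] - csum[:-w]) / w
        full[w - 1 :] = True
    return PhysioQC(
        included=included,
        error_free_fraction=frac,
        clean_values=clean,
        smoothed=smoothed,
        full_window=full,
        window=w,
    )
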