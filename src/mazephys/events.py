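"""Event-aligned analyses: PSTHs and tone-responsiveness classification.

Laser pulses (5 ms, delivered at 10 Hz) are analysed with a fine-binned
peristimulus time histogram over a 100-ms window centred on pulse
onset.  Fear-conditioned tones (20 s) are analysed trial-by-trial: the
firing rate during each tone is compared with the rate in the 40 s
immediately preceding it, across trials, with a two-sided rank-sum
test; units with p below the criterion are excited or inhibited
according to the direction of the median rate change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrain
from .stats import binomial_p, rank_sum_p

__all__ = [
    "EventSeries",
    "PSTH",
    "ToneResponse",
    "ResponseTally",
    "build_psth",
    "classify_tone_response",
    "response_direction_tally",
]

TONE_DURATION = 20.0       # s
BASELINE_DURATION = 40.0   # s preceding each tone
PSTH_WINDOW = 0.100        # s, centred on pulse onset
PSTH_BIN = 0.001           # s
ALPHA = 0.05

EXCITED = "excited"
INHIBITED = "inhibited"
NONE = "none"


@dataclass
class EventSeries:
    """Stimulus onsets with a common per-event duration.

    ``kind`` is ``"tone"`` (duration 20 s) or ``"laser_pulse"``
    (duration 5 ms); tones must not overlap.
    """

    kind: str
    onsets: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("event onsets must be sorted")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == "tone" and self.onsets.size > 1:
            if np.any(np.diff(self.onsets) < self.duration):
                raise ValueError("tone events overlap")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def offsets(self) -> np.ndarray:
        return self.onsets + self.duration


@dataclass
class PSTH:
    """Event-aligned binned firing rate (Hz)."""

    bin_edges: np.ndarray  # s, relative to event onset
    rates: np.ndarray      # Hz per bin
    counts: np.ndarray     # raw spike counts per bin
    n_events: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def build_psth(
    spikes: SpikeTrain,
    events: EventSeries,
    window: float = PSTH_WINDOW,
    bin_width: float = PSTH_BIN,
) -> PSTH:
    """PSTH over a window centred at event onset.

    Bins are half-open ``[left, right)`` in event-relative time, so a
    spike exactly at an onset lands in the bin containing 0.  Rates are
    counts / (n_events * bin_width).
    """
    if events.n_events == 0:
        raise ValueError("PSTH needs at least one event")
    n_bins = window / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the window")
    n_bins = int(round(n_bins))
    edges = -window / 2.0 + bin_width * np.arange(n_bins + 1)

    # Slice per event with searchsorted (no outer product), then
    # floor-index rather than np.histogram so every bin — including the
    # last — is half-open.
    counts = np.zeros(n_bins, dtype=np.int64)
    st = spikes.spike_times
    for onset in events.onsets:
        lo = np.searchsorted(st, onset + edges[0], side="left")
        hi = np.searchsorted(st, onset + edges[-1], side="left")
        if hi > lo:
            rel = st[lo:hi] - onset
            idx = np.floor((rel - edges[0]) / bin_width).astype(int)
            idx = np.clip(idx, 0, n_bins - 1)
            counts += np.bincount(idx, minlength=n_bins)
    rates = counts / (events.n_events * bin_width)
    return PSTH(bin_edges=edges, rates=rates, counts=counts,
                n_events=events.n_events)


@dataclass
class ToneResponse:
    unit_id: str
    tone_rates: np.ndarray      # Hz, one per trial
    baseline_rates: np.ndarray  # Hz, one per trial
    p_value: float
    label: str                  # excited | inhibited | none
    n_trials_used: int
    n_trials_dropped: int


def classify_tone_response(
    spikes: SpikeTrain,
    tones: EventSeries,
    tone_duration: float | None = None,
    baseline_duration: float = BASELINE_DURATION,
    alpha: float = ALPHA,
) -> ToneResponse:
    """Per-trial tone vs baseline rate comparison for one unit.

    Each trial contributes one tone-period rate and one baseline rate
    (the ``baseline_duration`` seconds preceding tone onset, truncated
    at session start and at the end of the previous tone).  Trials
    whose baseline truncates to zero length are dropped.  The two rate
    samples are compared across trials with a two-sided rank-sum test;
    the unit is excited/inhibited when p < ``alpha``, by the sign of
    the median rate difference.
    """
    if tones.n_events < 2:
        raise ValueError("tone classification needs >= 2 trials")
    dur = tones.duration if tone_duration is None else tone_duration

    tone_rates, base_rates = [], []
    dropped = 0
    prev_offset = 0.0
    for onset in tones.onsets:
        base_start = max(onset - baseline_duration, prev_offset, 0.0)
        base_len = onset - base_start
        prev_offset = onset + dur
        if base_len <= 0:
            dropped += 1
            continue
        n_tone = np.count_nonzero(
            (spikes.spike_times >= onset) & (spikes.spike_times < onset + dur)
        )
        n_base = np.count_nonzero(
            (spikes.spike_times >= base_start) & (spikes.spike_times < onset)
        )
        tone_rates.append(n_tone / dur)
        base_rates.append(n_base / base_len)

    tone_rates = np.asarray(tone_rates)
    base_rates = np.asarray(base_rates)
    if tone_rates.size < 2:
        raise ValueError("fewer than 2 usable trials after baseline truncation")

    p = rank_sum_p(tone_rates, base_rates)
    if p < alpha:
        label = (
            EXCITED
            if np.median(tone_rates) > np.median(base_rates)
            else INHIBITED
        )
        if np.median(tone_rates) == np.median(base_rates):
            label = NONE
    else:
        label = NONE
    return ToneResponse(
        unit_id=spikes.unit_id,
        tone_rates=tone_rates,
        baseline_rates=base_rates,
        p_value=p,
        label=label,
        n_trials_used=int(tone_rates.size),
        n_trials_dropped=dropped,
    )


@dataclass
class ResponseTally:
    n_excited: int
    n_inhibited: int
    n_none: int
    binomial_p: float | None  # inhibited vs excited among responsive cells


def response_direction_tally(
    responses: list[ToneResponse],
) -> ResponseTally:
    """Counts of excited/inhibited/unresponsive cells and an exact
    binomial test (p0 = 0.5) of inhibition vs excitation among the
    responsive cells.  With no responsive cells the tally is reported
    and the p-value left uncomputed."""
    n_exc = sum(r.label == EXCITED for r in responses)
    n_inh = sum(r.label == INHIBITED for r in responses)
    n_none = sum(r.label == NONE for r in responses)
    n_resp = n_exc + n_inh
    p = binomial_p(n_inh, n_resp) if n_resp >= 1 else None
    return ResponseTally(
        n_excited=n_exc, n_inhibited=n_inh, n_none=n_none, binomial_p=p
    )
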