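"""Seeded generators for every data modality the analyses consume.

The generators emulate the statistical structure the analyses assume,
not the biophysics that produces it:

* maze exploration is a semi-Markov dwell process — exponential dwell
  in each compartment, transitions along the maze topology (plus-maze
  arms connect only through the centre) — which reproduces the
  closed-arm occupancy bias of an anxious rodent without modelling
  locomotion;
* spiking is an inhomogeneous Poisson process whose instantaneous rate
  is a base rate times a compartment multiplier (times a tone
  multiplier inside tone windows), simulated exactly by thinning;
* voltage-clamp sweeps are Gaussian noise plus an optional alpha-shaped
  current at a fixed latency after the light pulse;
* oximetry streams are 1-Hz samples with slow drift, white noise, and
  Bernoulli motion-error flags.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CLOSED_ARM_LABELS,
    EPM_ARM_LABELS,
    OPEN_ARM_LABELS,
    SpikeTrain,
    Trajectory,
)
from .events import EventSeries
from .evoked import PhysioTrace, Sweep

__all__ = [
    "BehaviourModel",
    "FiringModel",
    "UnitSpec",
    "SimConfig",
    "SessionData",
    "substream",
    "simulate_trajectory",
    "simulate_spiketrain",
    "simulate_sweeps",
    "simulate_oximetry",
    "default_roster",
    "simulate_session",
]

TRACKING_RATE = 30.0  # Hz

# Session layout (s): 5 min home cage, 20 min plus maze, 10 min light/dark.
HOME_DURATION = 300.0
EPM_DURATION = 1200.0
LDT_DURATION = 600.0


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for a named stage/unit substream.

    Streams are keyed by integers, so results never depend on the
    order in which units or stages are processed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

@dataclass
class BehaviourModel:
    """Semi-Markov dwell model over named compartments.

    ``dwell_means`` holds the exponential mean dwell time (s) per
    compartment; ``transitions`` maps each compartment to candidate
    successors with probabilities.  The plus-maze factory routes every
    arm through the centre, so arm-to-arm jumps cannot occur.
    """

    dwell_means: dict[str, float]
    transitions: dict[str, list[tuple[str, float]]]
    start_label: str

    def __post_init__(self) -> None:
        for lab, mean in self.dwell_means.items():
            if mean <= 0:
                raise ValueError(f"dwell mean for {lab!r} must be > 0")
        for lab, outs in self.transitions.items():
            total = sum(p for _, p in outs)
            if not outs or abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition probs for {lab!r} must sum to 1")
            for nxt, _ in outs:
                if nxt not in self.dwell_means:
                    raise ValueError(f"unknown successor {nxt!r}")
        if self.start_label not in self.dwell_means:
            raise ValueError("unknown start label")

    @classmethod
    def epm(
        cls,
        closed_bias: float = 4.0,
        center_dwell: float = 3.0,
        arm_dwell: float = 10.0,
    ) -> "BehaviourModel":
        """Plus-maze exploration with closed-arm avoidance bias.

        ``closed_bias`` multiplies the closed-arm dwell mean; with the
        defaults (bias 4) the stationary closed-arm occupancy fraction
        is about 0.71, i.e. a typically anxious animal.  Sessions start
        in a closed arm, where animals are placed.
        """
        dwell = {"center": center_dwell}
        for lab in CLOSED_ARM_LABELS:
            dwell[lab] = arm_dwell * closed_bias
        for lab in OPEN_ARM_LABELS:
            dwell[lab] = arm_dwell
        trans = {"center": [(lab, 0.25) for lab in EPM_ARM_LABELS]}
        for lab in EPM_ARM_LABELS:
            trans[lab] = [("center", 1.0)]
        return cls(dwell, trans, start_label="closed_left")

    @classmethod
    def ldt(
        cls, dark_bias: float = 2.0, compartment_dwell: float = 15.0
    ) -> "BehaviourModel":
        """Light/dark box with a dark-compartment dwell bias."""
        dwell = {
            "dark": compartment_dwell * dark_bias,
            "light": compartment_dwell,
        }
        trans = {"dark": [("light", 1.0)], "light": [("dark", 1.0)]}
        return cls(dwell, trans, start_label="dark")

    @classmethod
    def single_compartment(cls, label: str = "home") -> "BehaviourModel":
        return cls({label: 60.0}, {label: [(label, 1.0)]}, start_label=label)


def simulate_trajectory(
    model: BehaviourModel,
    duration: float,
    rate: float = TRACKING_RATE,
    rng=None,
) -> Trajectory:
    """Sample the dwell process at the tracking rate; labelled output."""
    rng = _as_rng(rng)
    seg_starts = [0.0]
    seg_labels = [model.start_label]
    t = rng.exponential(model.dwell_means[model.start_label])
    state = model.start_label
    while t < duration:
        outs = model.transitions[state]
        names = [n for n, _ in outs]
        probs = np.array([p for _, p in outs])
        state = names[rng.choice(len(names), p=probs)]
        seg_starts.append(t)
        seg_labels.append(state)
        t += rng.exponential(model.dwell_means[state])

    sample_times = np.arange(0.0, duration, 1.0 / rate)
    idx = np.searchsorted(seg_starts, sample_times, side="right") - 1
    labels = np.array(seg_labels, dtype=object)[idx]
    return Trajectory(
        sample_times=sample_times,
        session_duration=duration,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

@dataclass
class FiringModel:
    """Compartment- and tone-modulated Poisson firing for one unit.

    The instantaneous rate is ``base_rate`` times the multiplier of the
    currently occupied compartment (1 where unlisted) times
    ``tone_multiplier`` inside tone windows.
    """

    base_rate: float
    compartment_multipliers: dict[str, float] = field(default_factory=dict)
    tone_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.tone_multiplier < 0:
            raise ValueError("rates and multipliers must be >= 0")
        for lab, m in self.compartment_multipliers.items():
            if m < 0:
                raise ValueError(f"negative multiplier for {lab!r}")

    def multiplier(self, label: str) -> float:
        return self.compartment_multipliers.get(label, 1.0)


def _in_event(t: np.ndarray, events: EventSeries) -> np.ndarray:
    idx = np.searchsorted(events.onsets, t, side="right") - 1
    inside = idx >= 0
    inside[inside] &= (
        t[inside] < events.onsets[idx[inside]] + events.duration
    )
    return inside


def simulate_spiketrain(
    traj: Trajectory,
    firing: FiringModel,
    events: EventSeries | None = None,
    rng=None,
    unit_id: str = "unit",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes via exact thinning.

    Candidate spikes are drawn homogeneously at the ceiling rate and
    accepted with probability rate(t)/ceiling, where rate(t) follows
    the trajectory's compartment labels (zero-order hold) and any tone
    windows.
    """
    if traj.labels is None:
        raise ValueError("simulate_spiketrain needs a labelled trajectory")
    rng = _as_rng(rng)
    duration = traj.session_duration
    labels = np.asarray(traj.labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    mults = {lab: firing.multiplier(lab) for lab in uniq}
    ceiling = firing.base_rate * max(mults.values(), default=1.0)
    ceiling *= max(1.0, firing.tone_multiplier)
    if ceiling <= 0:
        return SpikeTrain(unit_id, np.empty(0), duration)

    n_cand = rng.poisson(ceiling * duration)
    if n_cand == 0:
        return SpikeTrain(unit_id, np.empty(0), duration)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))

    idx = np.searchsorted(traj.sample_times, t_cand, side="right") - 1
    idx = np.clip(idx, 0, labels.size - 1)
    mult_arr = np.array([mults[lab] for lab in uniq])
    lab_to_i = {lab: i for i, lab in enumerate(uniq)}
    lab_idx = np.array([lab_to_i[lab] for lab in labels[idx]])
    rate = firing.base_rate * mult_arr[lab_idx]
    if events is not None:
        rate = np.where(
            _in_event(t_cand, events), rate * firing.tone_multiplier, rate
        )
    accept = rng.uniform(0.0, 1.0, n_cand) < rate / ceiling
    return SpikeTrain(unit_id, t_cand[accept], duration)


# ---------------------------------------------------------------------------
# Voltage-clamp sweeps and oximetry
# ---------------------------------------------------------------------------

def simulate_sweeps(
    n_traces: int,
    peak_amplitude: float,
    peak_latency: float = 0.020,
    noise_sd: float = 2.0,
    rng=None,
    sampling_rate: float = 10_000.0,
    sweep_duration: float = 0.3,
    pulse_onset: float = 0.15,
    alpha_tau: float = 0.005,
) -> list[Sweep]:
    """Sweeps of Gaussian noise plus an alpha-shaped current.

    The deflection is an alpha function ``A * (s/tau) * exp(1 - s/tau)``
    with rise constant ``alpha_tau`` whose onset sits at
    ``peak_latency - alpha_tau`` after the pulse, so the peak (amplitude
    ``peak_amplitude``, pA) lands exactly at ``peak_latency`` (s) after
    the pulse and the trace is flat before the onset.  Amplitude 0
    yields pure noise.
    """
    rng = _as_rng(rng)
    tau = min(alpha_tau, peak_latency)
    onset = pulse_onset + peak_latency - tau
    n = int(round(sweep_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    dt = t - onset
    kernel = np.zeros(n)
    pos = dt > 0
    kernel[pos] = (dt[pos] / tau) * np.exp(1.0 - dt[pos] / tau)
    out = []
    for _ in range(n_traces):
        samples = rng.normal(0.0, noise_sd, n) + peak_amplitude * kernel
        out.append(
            Sweep(
                samples=samples,
                sampling_rate=sampling_rate,
                pulse_onset=pulse_onset,
                baseline_window=(0.0, pulse_onset),
            )
        )
    return out


def simulate_oximetry(
    duration: float,
    base_rate: float = 200.0,
    error_fraction: float = 0.1,
    noise_sd: float = 8.0,
    drift_sd: float = 1.0,
    kind: str = "respiratory",
    rng=None,
) -> PhysioTrace:
    """1-Hz physiological stream with motion-error flags.

    The default base rate (200 breaths/min) sits in the typical murine
    resting range; drift is a random walk on top of white noise.
    ``error_fraction`` of samples are flagged as motion artefacts.
    """
    if not 0.0 <= error_fraction <= 1.0:
        raise ValueError("error_fraction must be in [0, 1]")
    rng = _as_rng(rng)
    n = int(round(duration))
    drift = np.cumsum(rng.normal(0.0, drift_sd, n))
    values = base_rate + drift + rng.normal(0.0, noise_sd, n)
    errors = rng.uniform(size=n) < error_fraction
    return PhysioTrace(values=values, error_flags=errors, kind=kind)


# ---------------------------------------------------------------------------
# Whole-session roster
# ---------------------------------------------------------------------------

@dataclass
class UnitSpec:
    unit_id: str
    firing: FiringModel


@dataclass
class SimConfig:
    """One simulated recording day: home cage, plus maze, light/dark box.

    ``units`` carries one firing model per unit; ``default_roster``
    builds the standard 38-unit population.
    """

    seed: int
    units: list[UnitSpec]
    home_duration: float = HOME_DURATION
    epm_duration: float = EPM_DURATION
    ldt_duration: float = LDT_DURATION
    tracking_rate: float = TRACKING_RATE
    closed_bias: float = 4.0
    dark_bias: float = 2.0
    n_tones: int = 10
    tone_duration: float = 20.0
    tone_interval: float = 70.0

    def __post_init__(self) -> None:
        for d in (self.home_duration, self.epm_duration, self.ldt_duration):
            if d <= 0:
                raise ValueError("durations must be > 0")


def default_roster(
    n_units: int = 38,
    closed_fraction: float = 0.45,
    open_fraction: float = 0.15,
    inhibited_fraction: float = 0.40,
    excited_fraction: float = 0.10,
    rng=None,
) -> list[UnitSpec]:
    """Standard population: mostly closed-arm-preferring, tone-inhibited.

    Each unit carries an "anxiety multiplier" applied in the anxiogenic
    compartments (open arms, light box half): below 1 for
    closed-preferring units, above 1 for open-preferring, 1 for
    untuned.  Tone multipliers mark a subpopulation as tone-inhibited
    (suppression to ~0.25x) and a smaller one as tone-excited.
    Base rates are log-normal around ~4 Hz.
    """
    rng = _as_rng(rng)
    n_closed = int(round(n_units * closed_fraction))
    n_open = int(round(n_units * open_fraction))
    n_inh = int(round(n_units * inhibited_fraction))
    n_exc = int(round(n_units * excited_fraction))

    units = []
    for i in range(n_units):
        base = float(rng.lognormal(mean=np.log(4.0), sigma=0.5))
        if i < n_closed:
            anx = float(rng.uniform(0.3, 0.6))   # quieter in open/light
        elif i < n_closed + n_open:
            anx = float(rng.uniform(1.8, 3.0))   # louder in open/light
        else:
            anx = 1.0
        if i < n_inh:
            tone = 0.25
        elif i < n_inh + n_exc:
            tone = 2.5
        else:
            tone = 1.0
        mults = {
            "open_up": anx,
            "open_down": anx,
            "light": anx,
        }
        units.append(
            UnitSpec(
                unit_id=f"unit{i:03d}",
                firing=FiringModel(
                    base_rate=base,
                    compartment_multipliers=mults,
                    tone_multiplier=tone,
                ),
            )
        )
    return units


@dataclass
class SessionData:
    config: SimConfig
    home_trajectory: Trajectory
    epm_trajectory: Trajectory
    ldt_trajectory: Trajectory
    tones: EventSeries
    home_spikes: list[SpikeTrain]
    epm_spikes: list[SpikeTrain]
    ldt_spikes: list[SpikeTrain]
    tone_spikes: list[SpikeTrain]


# fixed stage keys for the seed substreams
_STAGE_HOME, _STAGE_EPM, _STAGE_LDT, _STAGE_TONE = 1, 2, 3, 4


def simulate_session(config: SimConfig) -> SessionData:
    """Generate every paradigm for the whole roster, reproducibly.

    The config seed fans out into named substreams per stage and unit,
    so adding or reordering units never perturbs the others.
    """
    home_traj = simulate_trajectory(
        BehaviourModel.single_compartment("home"),
        config.home_duration,
        config.tracking_rate,
        substream(config.seed, _STAGE_HOME, 0),
    )
    epm_traj = simulate_trajectory(
        BehaviourModel.epm(closed_bias=config.closed_bias),
        config.epm_duration,
        config.tracking_rate,
        substream(config.seed, _STAGE_EPM, 0),
    )
    ldt_traj = simulate_trajectory(
        BehaviourModel.ldt(dark_bias=config.dark_bias),
        config.ldt_duration,
        config.tracking_rate,
        substream(config.seed, _STAGE_LDT, 0),
    )
    tone_onsets = (
        np.arange(config.n_tones) * config.tone_interval + 60.0
    )
    tones = EventSeries("tone", tone_onsets, config.tone_duration)
    tone_session_duration = float(tone_onsets[-1] + 60.0)
    tone_traj = simulate_trajectory(
        BehaviourModel.single_compartment("conditioning_box"),
        tone_session_duration,
        config.tracking_rate,
        substream(config.seed, _STAGE_TONE, 0),
    )

    home_sp, epm_sp, ldt_sp, tone_sp = [], [], [], []
    for i, spec in enumerate(config.units, start=1):
        home_sp.append(
            simulate_spiketrain(
                home_traj, spec.firing,
                rng=substream(config.seed, _STAGE_HOME, i),
                unit_id=spec.unit_id,
            )
        )
        epm_sp.append(
            simulate_spiketrain(
                epm_traj, spec.firing,
                rng=substream(config.seed, _STAGE_EPM, i),
                unit_id=spec.unit_id,
            )
        )
        ldt_sp.append(
            simulate_spiketrain(
                ldt_traj, spec.firing,
                rng=substream(config.seed, _STAGE_LDT, i),
                unit_id=spec.unit_id,
            )
        )
        tone_sp.append(
            simulate_spiketrain(
                tone_traj, spec.firing, events=tones,
                rng=substream(config.seed, _STAGE_TONE, i),
                unit_id=spec.unit_id,
            )
        )
    return SessionData(
        config=config,
        home_trajectory=home_traj,
        epm_trajectory=epm_traj,
        ldt_trajectory=ldt_traj,
        tones=tones,
        home_spikes=home_sp,
        epm_spikes=epm_sp,
        ldt_spikes=ldt_sp,
        tone_spikes=tone_sp,
    )
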