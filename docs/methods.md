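# Methods

This note records the models, conventions and numerical choices behind
`mazephys`, and what the synthetic-data generators do and do not
emulate.

## Session model and rate bookkeeping

A session couples a position trajectory (nominally 30 Hz) with spike
trains, over a maze geometry of axis-aligned rectangular compartments.
Rectangles are half-open on their upper edges, so abutting compartments
never both contain a point; positions outside every compartment are
kept and labelled `outside`.

Occupancy per compartment is (number of samples so labelled) × (sample
interval); each spike is attributed to the nearest-*preceding*
trajectory sample (zero-order hold over half-open intervals
[tᵢ, tᵢ₊₁)). This is deterministic and measures spikes with the same
clock as occupancy. Spikes preceding the first sample, or attributed to
`outside` samples, enter no compartment count. The whole-session mean
rate is n_spikes / session_duration — the full duration, centre time
and out-of-maze gaps included, because the fold-rate normalisation is
against firing "in the whole maze". Per-compartment rates with zero
occupancy are NaN, never silently zero; units with a zero mean rate or
an unvisited arm are excluded from scoring rather than imputed.

## Arm-selectivity score

score = (A − B)/(A + B) with A the mean absolute fold-rate difference
between arms of different types and B within types (see README for the
expanded form). Numerical conventions:

* A + B = 0 (identical rates in all four arms) ⇒ score 0, matching the
  interpretation of zero as "same firing everywhere" despite the
  formula's 0/0.
* The score is bounded in [−1, 1], invariant to rescaling all fold
  rates, and invariant to swapping arms within a type or swapping the
  two types wholesale; these are tested as properties.

### Shuffle null

Per unit, 500 replicates each score n timestamps drawn uniformly
*without replacement* from the trajectory's sample times against the
same trajectory. Drawing from sample times (rather than continuous
time) inherits the occupancy structure exactly and makes the draw a
finite-population problem. Because the score depends on a replicate
only through its per-compartment counts, the ensemble is sampled from
the equivalent multivariate hypergeometric distribution over
compartment sample counts — distributionally exact and about two
orders of magnitude faster than materialising timestamps; a test
verifies the equivalence against a literal timestamp-draw
implementation.

The per-unit empirical p uses the add-one estimator
(1 + #{null ≥ observed}) / (1 + reps), which is never exactly zero and
is calibrated for position-independent units (tested: the fraction of
p < 0.05 among 200 untuned Poisson units stays inside the exact
binomial 95% band around 0.05).

### Classification and population tests

Score ≤ 0 ⇒ not task-related; otherwise closed- or open-arm-preferring
by the larger pooled arm-type rate (total spikes / total time across
the two arms of a type). An exact tie with a positive score is labelled
not task-related — conservative, and only reachable with quantised
counts. The population-level rank-sum test compares observed scores
with the *pooled* null scores of all units (reps × units values); the
closed-vs-open binomial test is exact, two-sided at p₀ = 0.5
(direction is reported separately).

Rank-sum convention throughout the package: exact enumeration when
both groups have ≤ 10 observations and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation with continuity
correction; all observations identical ⇒ p = 1.

### Stability and cross-paradigm analyses

Stability splits the session at its midpoint and computes
pooled open-arm / closed-arm rate ratios per half, keeping units with
≥ 10 spikes per arm type per half, then Spearman-correlates the two
ratio vectors (≥ 3 units required). The cross-paradigm analysis
expresses EPM open-arm and light/dark light-compartment rates as fold
increase over the unit's home-cage rate; units with zero home-cage
rate have no defined fold increase and are excluded with a log entry.

## Event-aligned analyses

PSTHs use half-open bins (default 1 ms over a 100-ms window centred on
pulse onset, fine enough to resolve 5-ms pulses); event-relative time
0 is the onset, and a spike exactly at an onset lands in the bin
containing 0. Rates are counts / (n_events × bin width); total spike
mass is conserved (tested).

Tone responsiveness is decided across trials: each 20-s tone
contributes one tone rate and one baseline rate (the 40 s before
onset, truncated at session start and at the previous tone's offset;
trials whose baseline truncates to nothing are dropped). A two-sided
rank-sum across trials at α = 0.05 gates the excited/inhibited label,
with direction by the median rate change. The trial — not the spike or
the time bin — is the sampling unit, which keeps the test valid under
within-trial rate autocorrelation.

## Signal decision rules

* Evoked responses: sweeps are baseline-subtracted individually and
  averaged; the peak is the largest-magnitude deflection (both
  polarities — both inward and outward currents occur) in
  (pulse, pulse + 50 ms]; the noise s.d. is computed on the *averaged*
  trace's baseline, since the threshold is applied to the averaged
  trace's peak. Responder iff |peak| > 5 s.d. The rule's false-positive
  rate on pure-noise ensembles is below 5% (tested over 500 seeded
  ensembles with 150-ms baselines).
* Multiunit events: crossings of baseline mean ± 3 s.d. with a 1-ms
  dead time (a standard refractory guard; the rule itself does not fix
  one).
* Oximetry QC: error-flagged samples are removed first; smoothing is a
  trailing moving average of 10 samples (respiratory) or 5 (heart);
  leading samples with an incomplete window pass through unsmoothed
  and are flagged. Sessions are included iff ≥ 30% of samples are
  error-free.

## Synthetic data: what it emulates, and what it does not

Exploration is a semi-Markov process — exponential dwell per
compartment, transitions along the maze topology (plus-maze arms
connect only through the centre; light/dark compartments alternate).
Defaults: centre dwell 3 s, arm dwell 10 s, closed-arm dwell ×4, which
puts the stationary closed-arm occupancy near 0.71 — a typically
anxious animal; sessions start in a closed arm, where animals are
placed. The light/dark box uses a ×2 dark bias. These are free
parameters: no quantitative occupancy values are available to fit, so
they are chosen once as field-plausible and exposed in the config.

Spiking is inhomogeneous Poisson via exact thinning; the rate is a base
rate × compartment multiplier × tone multiplier. The default 38-unit
roster has 45% closed-preferring units (anxiogenic-compartment
multiplier drawn in 0.3–0.6, applied identically in open arms and the
lit compartment so that cross-paradigm correlation is a real property
of the population), 15% open-preferring (×1.8–3.0), the rest untuned;
base rates are log-normal around 4 Hz; 40% of units are tone-inhibited
(×0.25) and 10% tone-excited (×2.5), matching the qualitative
preponderance of inhibition. Session layout: 5 min home cage, 20 min
plus maze, 10 min light/dark, plus a 10-tone recall session (tones
every 70 s, allowing full 40-s baselines).

Sweeps are Gaussian noise plus an alpha-shaped current with a 5-ms
rise constant whose onset sits at (latency − 5 ms) after the pulse, so
the peak lands exactly at the requested latency and a 60-ms-latency
current leaves the 50-ms decision window clean. Oximetry is a random
walk plus white noise around 200 breaths/min with Bernoulli error
flags.

Not emulated: locomotor kinematics and speed/head-direction coding,
correlated population activity, bursting or refractory structure,
waveform shape, drift or unit loss, and real artefact statistics.
Passing the recovery and calibration tests therefore shows the
*analysis chain* is correct and calibrated under its stated
assumptions, not that those assumptions hold in any particular
recording.

All generators are pure functions of (config, seed); a session-level
seed fans out into integer-keyed substreams per stage and unit, so
results are independent of processing order.

## Problem sizes

Calibration and recovery analyses in the test suite use 200 untuned
units (20-min sessions, 500-replicate nulls), 100 closed-biased units,
30 + 200 units for tone recovery/calibration, and 500 sweep ensembles
per evoked-rule condition; these sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping the suite fast.

## Known limitations

* The score is undefined (unit excluded) whenever any arm goes
  unvisited; very short or extremely biased sessions can exclude many
  units.
* The rank-sum normal approximation is used whenever ties are present,
  including small tied samples, where it is approximate.
* Tone baselines shorter than 40 s (closely spaced tones) are used at
  their truncated length rather than dropped, weighting trials
  unequally.
* `EventSeries` carries one duration for all events; variable-duration
  protocols need one series per duration.
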