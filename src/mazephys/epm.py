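"""Arm-selectivity scoring on the elevated plus maze.

The statistic quantifies how much of a unit's firing-rate variation
across the four maze arms is explained by arm *type* (closed vs open)
rather than by arm *identity*.  With fold rates ``FL, FR`` (closed
left/right) and ``FU, FD`` (open up/down), each a per-arm rate divided
by the unit's whole-session mean rate,

    A = 0.25 * (|FL-FU| + |FL-FD| + |FR-FU| + |FR-FD|)   (between types)
    B = 0.50 * (|FL-FR| + |FU-FD|)                       (within types)

    score = (A - B) / (A + B)

A score of 1 means every difference between arms is a difference
between arm types (equal high rates in both closed arms, or in both
open arms); 0 means equal firing in all compartments (the 0/0 case is
defined as 0); negative scores indicate selectivity for arm identity
that crosses types.

Chance levels are estimated per unit by re-scoring ``n`` timestamps
drawn at random, without replacement, from the trajectory's own
position samples — the draw inherits the occupancy structure, so a
unit firing uniformly in time scores at chance.  Because the score
depends on the drawn timestamps only through their per-compartment
counts, the null ensemble is sampled exactly (and fast) from the
multivariate hypergeometric distribution over compartment sample
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CLOSED_ARM_LABELS,
    EPM_ARM_LABELS,
    OPEN_ARM_LABELS,
    OUTSIDE,
    CompartmentRates,
    SpikeTrain,
    Trajectory,
    compartment_rates,
    pooled_rate,
)
from .stats import binomial_p, rank_sum_p, spearman

__all__ = [
    "UnscorableUnit",
    "FoldRates",
    "EPMScoreResult",
    "PopulationSummary",
    "StabilityResult",
    "CrossParadigmResult",
    "fold_rates",
    "epm_score",
    "shuffle_null",
    "empirical_p_value",
    "score_unit",
    "classify_unit",
    "population_score_test",
    "arm_preference_binomial",
    "stability_analysis",
    "cross_paradigm_correlation",
]

NOT_TASK_RELATED = "not_task_related"
CLOSED_PREFERRING = "closed_preferring"
OPEN_PREFERRING = "open_preferring"

DEFAULT_REPS = 500


class UnscorableUnit(ValueError):
    """Unit excluded from scoring (zero mean rate or unvisited arm)."""


@dataclass(frozen=True)
class FoldRates:
    """Per-arm firing rate divided by the whole-session mean rate."""

    left: float   # closed left
    right: float  # closed right
    up: float     # open up
    down: float   # open down

    def as_array(self) -> np.ndarray:
        return np.array([self.left, self.right, self.up, self.down])


@dataclass
class EPMScoreResult:
    unit_id: str
    fold: FoldRates
    a: float  # mean cross-type fold-rate difference
    b: float  # mean within-type fold-rate difference
    score: float
    null_scores: np.ndarray | None = None
    empirical_p: float | None = None
    label: str | None = None


def fold_rates(rates: CompartmentRates) -> FoldRates:
    """Fold-firing rates for the four arms.

    Raises :class:`UnscorableUnit` when the unit's mean rate is zero or
    any arm was never occupied — such units are excluded, not imputed.
    """
    if rates.mean_rate <= 0:
        raise UnscorableUnit(f"{rates.unit_id}: zero mean rate")
    for lab in EPM_ARM_LABELS:
        if not rates.occupied(lab):
            raise UnscorableUnit(f"{rates.unit_id}: arm {lab} never occupied")
    r = {lab: rates.rates[lab] / rates.mean_rate for lab in EPM_ARM_LABELS}
    return FoldRates(
        left=r["closed_left"],
        right=r["closed_right"],
        up=r["open_up"],
        down=r["open_down"],
    )


def epm_score(f: FoldRates) -> tuple[float, float, float]:
    """Score with its between-type (A) and within-type (B) components.

    Returns ``(score, A, B)``; the degenerate case ``A + B == 0``
    (identical rates everywhere) is defined as score 0.
    """
    fl, fr, fu, fd = f.left, f.right, f.up, f.down
    a = 0.25 * (abs(fl - fu) + abs(fl - fd) + abs(fr - fu) + abs(fr - fd))
    b = 0.5 * (abs(fl - fr) + abs(fu - fd))
    score = 0.0 if a + b == 0 else (a - b) / (a + b)
    return score, a, b


def _scores_from_arm_counts(
    arm_counts: np.ndarray,
    arm_occupancy: np.ndarray,
    mean_rate: float,
) -> np.ndarray:
    """Vectorised score for (reps, 4) arm spike counts, order L,R,U,D."""
    fold = arm_counts / arm_occupancy / mean_rate  # (reps, 4)
    fl, fr, fu, fd = fold[:, 0], fold[:, 1], fold[:, 2], fold[:, 3]
    a = 0.25 * (
        np.abs(fl - fu) + np.abs(fl - fd) + np.abs(fr - fu) + np.abs(fr - fd)
    )
    b = 0.5 * (np.abs(fl - fr) + np.abs(fu - fd))
    denom = a + b
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = (a[nz] - b[nz]) / denom[nz]
    return out


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def shuffle_null(
    n_spikes: int,
    traj: Trajectory,
    reps: int = DEFAULT_REPS,
    rng=None,
) -> np.ndarray:
    """Null ensemble of ``reps`` scores for a unit with ``n_spikes`` spikes.

    Each replicate scores ``n_spikes`` timestamps drawn uniformly
    without replacement from the trajectory's sample times against the
    same trajectory.  The score depends on a replicate only through the
    number of drawn timestamps landing in each compartment, so the
    per-compartment counts are drawn directly from the equivalent
    multivariate hypergeometric distribution.
    """
    if traj.labels is None:
        raise ValueError("shuffle_null needs a labelled trajectory")
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = np.asarray(traj.labels)
    if n_spikes > labels.size:
        raise ValueError(
            f"n_spikes={n_spikes} exceeds {labels.size} trajectory samples"
        )
    rng = _as_rng(rng)
    dt = traj.sample_interval

    # Compartment sample counts in a fixed order: the 4 arms, then the rest.
    uniq = list(dict.fromkeys(labels.tolist()))
    other = [l for l in uniq if l not in EPM_ARM_LABELS]
    order = list(EPM_ARM_LABELS) + other
    sample_counts = np.array(
        [np.count_nonzero(labels == lab) for lab in order], dtype=np.int64
    )
    if np.any(sample_counts[:4] == 0):
        missing = [l for l, c in zip(order[:4], sample_counts[:4]) if c == 0]
        raise UnscorableUnit(f"arms never occupied: {missing}")

    draws = rng.multivariate_hypergeometric(
        sample_counts, n_spikes, size=reps
    )  # (reps, n_compartments)
    arm_occ = sample_counts[:4].astype(float) * dt
    mean_rate = n_spikes / traj.session_duration
    return _scores_from_arm_counts(
        draws[:, :4].astype(float), arm_occ, mean_rate
    )


def empirical_p_value(observed: float, null_scores: np.ndarray) -> float:
    """Add-one empirical p: ``(1 + #{null >= observed}) / (1 + reps)``."""
    null_scores = np.asarray(null_scores, dtype=float)
    return (1.0 + np.count_nonzero(null_scores >= observed)) / (
        1.0 + null_scores.size
    )


def classify_unit(result: EPMScoreResult, rates: CompartmentRates) -> str:
    """Arm-preference label from the score and pooled arm-type rates.

    Scores <= 0 are not task-related.  Positive-score units are
    closed-preferring iff their pooled closed-arm rate exceeds the
    pooled open-arm rate, open-preferring if the reverse; an exact tie
    (possible with quantised counts) is conservatively not task-related.
    """
    if result.score <= 0:
        return NOT_TASK_RELATED
    closed = pooled_rate(rates, CLOSED_ARM_LABELS)
    open_ = pooled_rate(rates, OPEN_ARM_LABELS)
    if closed > open_:
        return CLOSED_PREFERRING
    if open_ > closed:
        return OPEN_PREFERRING
    return NOT_TASK_RELATED


def score_unit(
    spikes: SpikeTrain,
    traj: Trajectory,
    reps: int = DEFAULT_REPS,
    rng=None,
) -> EPMScoreResult:
    """Full per-unit analysis: fold rates, score, null ensemble, label."""
    rates = compartment_rates(spikes, traj)
    f = fold_rates(rates)
    score, a, b = epm_score(f)
    null = shuffle_null(spikes.n_spikes, traj, reps=reps, rng=rng)
    res = EPMScoreResult(
        unit_id=spikes.unit_id,
        fold=f,
        a=a,
        b=b,
        score=score,
        null_scores=null,
        empirical_p=empirical_p_value(score, null),
    )
    res.label = classify_unit(res, rates)
    return res


@dataclass
class PopulationSummary:
    n_units: int
    n_closed: int
    n_open: int
    n_not_task_related: int
    ranksum_p: float | None
    binomial_p: float | None

    def counts(self) -> dict[str, int]:
        return {
            CLOSED_PREFERRING: self.n_closed,
            OPEN_PREFERRING: self.n_open,
            NOT_TASK_RELATED: self.n_not_task_related,
        }


def population_score_test(observed, null) -> float:
    """Two-sided rank-sum p: observed scores vs pooled shuffle scores."""
    return rank_sum_p(observed, null)


def arm_preference_binomial(n_closed: int, n_open: int) -> float:
    """Exact two-sided binomial test of closed vs open preference (p0=0.5)."""
    n = n_closed + n_open
    if n < 1:
        raise ValueError("no arm-preferring units: test not computable")
    return binomial_p(n_closed, n)


def summarize_population(results: list[EPMScoreResult]) -> PopulationSummary:
    """Counts plus the two population tests over scored units."""
    n_closed = sum(r.label == CLOSED_PREFERRING for r in results)
    n_open = sum(r.label == OPEN_PREFERRING for r in results)
    n_ntr = sum(r.label == NOT_TASK_RELATED for r in results)
    scores = [r.score for r in results]
    pooled_null = np.concatenate(
        [r.null_scores for r in results if r.null_scores is not None]
    ) if any(r.null_scores is not None for r in results) else None
    ranksum = (
        population_score_test(scores, pooled_null)
        if scores and pooled_null is not None and pooled_null.size
        else None
    )
    binom = (
        arm_preference_binomial(n_closed, n_open)
        if (n_closed + n_open) >= 1
        else None
    )
    return PopulationSummary(
        n_units=len(results),
        n_closed=n_closed,
        n_open=n_open,
        n_not_task_related=n_ntr,
        ranksum_p=ranksum,
        binomial_p=binom,
    )


# ---------------------------------------------------------------------------
# Stability and cross-paradigm analyses
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Open/closed rate ratios per session half, for units passing the
    >= ``min_spikes``-per-arm-type-per-half filter, with their rank
    correlation across halves."""

    unit_ids: list[str]
    ratio_first_half: np.ndarray
    ratio_second_half: np.ndarray
    excluded_unit_ids: list[str]
    spearman_r: float | None
    spearman_p: float | None


def _arm_type_tallies(
    spikes: SpikeTrain, traj: Trajectory
) -> tuple[dict[str, int], dict[str, float]]:
    cr = compartment_rates(spikes, traj)
    counts = {
        "closed": sum(cr.spike_counts.get(l, 0) for l in CLOSED_ARM_LABELS),
        "open": sum(cr.spike_counts.get(l, 0) for l in OPEN_ARM_LABELS),
    }
    occ = {
        "closed": sum(cr.occupancy.get(l, 0.0) for l in CLOSED_ARM_LABELS),
        "open": sum(cr.occupancy.get(l, 0.0) for l in OPEN_ARM_LABELS),
    }
    return counts, occ


def stability_analysis(
    units: list[SpikeTrain],
    traj: Trajectory,
    min_spikes: int = 10,
) -> StabilityResult:
    """Within-session stability of arm-type preference.

    The session is split at its midpoint; for each half the pooled
    open-arm and closed-arm rates give an open/closed ratio.  Units
    with fewer than ``min_spikes`` spikes in either arm type in either
    half are excluded.  Spearman correlation across the included units
    (computed only when at least 3 remain) indexes stability.
    """
    if traj.session_duration < 120:
        raise ValueError("session too short to split into halves")
    mid = traj.session_duration / 2.0
    halves = [traj.time_slice(0.0, mid), traj.time_slice(mid, np.inf)]

    ids, r1, r2, excluded = [], [], [], []
    for unit in units:
        ratios = []
        ok = True
        for half, (t0, t1) in zip(halves, [(0.0, mid), (mid, np.inf)]):
            sub = unit.time_slice(t0, t1)
            counts, occ = _arm_type_tallies(sub, half)
            if counts["closed"] < min_spikes or counts["open"] < min_spikes:
                ok = False
                break
            if occ["closed"] <= 0 or occ["open"] <= 0:
                ok = False
                break
            ratios.append(
                (counts["open"] / occ["open"]) / (counts["closed"] / occ["closed"])
            )
        if ok:
            ids.append(unit.unit_id)
            r1.append(ratios[0])
            r2.append(ratios[1])
        else:
            excluded.append(unit.unit_id)

    if len(ids) >= 3:
        rho, p = spearman(r1, r2)
    else:
        rho = p = None
    return StabilityResult(
        unit_ids=ids,
        ratio_first_half=np.asarray(r1),
        ratio_second_half=np.asarray(r2),
        excluded_unit_ids=excluded,
        spearman_r=rho,
        spearman_p=p,
    )


@dataclass
class CrossParadigmResult:
    unit_ids: list[str]
    epm_open_fold: np.ndarray
    ldt_light_fold: np.ndarray
    excluded_unit_ids: list[str]
    spearman_r: float
    spearman_p: float


def cross_paradigm_correlation(
    unit_ids: list[str],
    epm_open_rate,
    ldt_light_rate,
    home_rate,
) -> CrossParadigmResult:
    """Correlation of anxiogenic-compartment rate changes across paradigms.

    For each unit the open-arm rate in the plus maze and the light-
    compartment rate in the light/dark box are expressed as fold
    increase over the unit's (non-anxiogenic) home-cage rate; Spearman
    correlation across units tests whether the two anxiogenic contexts
    recruit the same rate changes.  Units with zero home-cage rate have
    no defined fold increase and are excluded.
    """
    epm = np.asarray(epm_open_rate, dtype=float)
    ldt = np.asarray(ldt_light_rate, dtype=float)
    home = np.asarray(home_rate, dtype=float)
    if not (len(unit_ids) == epm.size == ldt.size == home.size):
        raise ValueError("per-unit vectors must share the roster length")
    keep = home > 0
    excluded = [u for u, k in zip(unit_ids, keep) if not k]
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 units with nonzero home-cage rate")
    fold_epm = epm[keep] / home[keep]
    fold_ldt = ldt[keep] / home[keep]
    rho, p = spearman(fold_epm, fold_ldt)
    return CrossParadigmResult(
        unit_ids=[u for u, k in zip(unit_ids, keep) if k],
        epm_open_fold=fold_epm,
        ldt_light_fold=fold_ldt,
        excluded_unit_ids=excluded,
        spearman_r=rho,
        spearman_p=p,
    )
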