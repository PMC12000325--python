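"""Circular statistics of trial phases.

The central statistic is the phase opposition product (POP). With the
amplitude-normalised analytic signal ``w_i / |w_i|`` per trial, the
inter-trial phase coherence over a trial set S is

    ITC = | sum_{i in S} w_i / |w_i| | / |S|

and the POP contrasts two conditions A and B against the pooled set:

    POP = ITC_A * ITC_B - ITC_ALL**2.

POP is large when the two conditions cluster at opposed angles: within-
condition coherence is then high while the pooled coherence collapses.
Amplitude never enters: only unit phase vectors are summed.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .containers import (
    AnalyticMap,
    ConfigurationError,
    LabelSet,
    PhasePartition,
    POPMap,
)

__all__ = [
    "itc",
    "pop",
    "pop_from_phases",
    "circular_mean",
    "optimal_phase_angle",
    "select_phase_trials",
    "circular_distance",
    "phase_binned_outcome_probability",
    "bootstrap_circular_distance_contrast",
    "detrend_ratings_by_delay",
]

_RESULTANT_EPS = 1e-12


def itc(vectors: np.ndarray, axis: int = 0, mask: np.ndarray | None = None) -> np.ndarray:
    """Inter-trial phase coherence of complex vectors along ``axis``.

    Vectors are normalised to unit length; zero-amplitude entries (undefined
    phase) raise unless excluded via ``mask`` (True = keep).
    """
    v = np.asarray(vectors, dtype=complex)
    if mask is not None:
        v = np.compress(np.asarray(mask, bool), v, axis=axis)
    mag = np.abs(v)
    if np.any(mag == 0):
        raise ValueError("zero-amplitude vector: phase undefined (mask it out)")
    unit = v / mag
    return np.abs(unit.mean(axis=axis))


def pop_from_phases(unit_vectors: np.ndarray, high_mask: np.ndarray):
    """POP along the first (trial) axis of an array of unit phase vectors.

    Returns ``(pop, itc_all, itc_a, itc_b)`` with the trailing array shape.
    """
    u = np.asarray(unit_vectors, dtype=complex)
    high_mask = np.asarray(high_mask, bool)
    low_mask = ~high_mask
    n_a, n_b = int(high_mask.sum()), int(low_mask.sum())
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("need >= 2 trials per condition")
    itc_all = np.abs(u.mean(axis=0))
    itc_a = np.abs(u[high_mask].mean(axis=0))
    itc_b = np.abs(u[low_mask].mean(axis=0))
    return itc_a * itc_b - itc_all**2, itc_all, itc_a, itc_b


def pop(analytic: AnalyticMap, labels: LabelSet, channel: int = 0) -> POPMap:
    """Phase opposition product per (frequency, time) for one channel."""
    used = labels.labels >= 0
    v = analytic.values[used, channel]  # (n_used, n_freqs, n_samples)
    mag = np.abs(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mag > 0, v / np.where(mag > 0, mag, 1.0), 0)
    high = labels.labels[used] == 1
    p, itc_all, itc_a, itc_b = pop_from_phases(u, high)
    return POPMap(
        pop=p,
        itc_all=itc_all,
        itc_a=itc_a,
        itc_b=itc_b,
        freqs=analytic.freqs,
        times=analytic.times,
        n=int(used.sum()),
        n_a=int(high.sum()),
        n_b=int((~high).sum()),
    )


def circular_mean(angles: np.ndarray) -> float:
    """Resultant-vector mean angle; raises if the resultant is degenerate."""
    r = np.mean(np.exp(1j * np.asarray(angles, dtype=float)))
    if np.abs(r) < _RESULTANT_EPS:
        raise ValueError("circular mean undefined: resultant length ~ 0")
    return float(np.angle(r))


def optimal_phase_angle(high_phases: np.ndarray, low_phases: np.ndarray) -> float:
    """Optimal phase: mean of the high-condition mean angle and the flipped
    low-condition mean angle, averaged as unit vectors (unweighted)."""
    a = circular_mean(high_phases)
    b = circular_mean(low_phases) + np.pi
    r = np.exp(1j * a) + np.exp(1j * b)
    if np.abs(r) < _RESULTANT_EPS:
        raise ValueError("optimal angle undefined: opposed direction estimates")
    return float(np.angle(r))


def circular_distance(a, b) -> np.ndarray | float:
    """Absolute circular distance in [0, pi] (difference wrapped to (-pi, pi])."""
    d = np.remainder(
        np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 2 * np.pi
    )
    out = np.minimum(d, 2 * np.pi - d)
    return float(out) if np.isscalar(a) and np.isscalar(b) else out


def select_phase_trials(
    phases: np.ndarray, optimal_angle: float, half_width: float = np.pi / 3
) -> PhasePartition:
    """Split trials into optimal / non-optimal by phase distance.

    Optimal trials lie strictly within ``half_width`` of ``optimal_angle``,
    non-optimal trials strictly within ``half_width`` of the antiphase;
    boundary trials and everything in between are excluded. With uniform
    phases and the default pi/3 half-width each group holds about a third
    of the trials.
    """
    phases = np.asarray(phases, dtype=float)
    d_opt = circular_distance(phases, optimal_angle)
    d_non = circular_distance(phases, optimal_angle + np.pi)
    optimal = np.flatnonzero(d_opt < half_width)
    non_optimal = np.flatnonzero(d_non < half_width)
    return PhasePartition(
        optimal_angle=float(optimal_angle),
        optimal=optimal,
        non_optimal=non_optimal,
        half_width=float(half_width),
    )


def phase_binned_outcome_probability(
    phases: np.ndarray,
    binary_outcomes: np.ndarray,
    n_bins: int = 6,
    reference_angle: float = 0.0,
    ci_level: float = 0.66,
):
    """Outcome probability in bins of circular distance to a reference angle.

    Bins partition [0, pi] into ``n_bins`` equal-width intervals of distance
    from ``reference_angle``. Returns a dict with bin centres, per-bin
    probability (NaN and flagged when empty), counts, and normal-approximation
    binomial confidence intervals at ``ci_level`` (default 66%).
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    phases = np.asarray(phases, dtype=float)
    y = np.asarray(binary_outcomes)
    d = circular_distance(phases, reference_angle)
    edges = np.linspace(0, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    prob = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            p = y[sel].mean()
            prob[b] = p
            se = np.sqrt(p * (1 - p) / counts[b])
            lo[b], hi[b] = p - z * se, p + z * se
    return {
        "bin_centres": 0.5 * (edges[:-1] + edges[1:]),
        "probability": prob,
        "count": counts,
        "ci_low": lo,
        "ci_high": hi,
        "empty_bins": np.flatnonzero(counts == 0),
    }


def _mean_angle_distance(x: np.ndarray, y: np.ndarray) -> float:
    return circular_distance(circular_mean(x), circular_mean(y))


def bootstrap_circular_distance_contrast(
    a_high: np.ndarray,
    a_low: np.ndarray,
    b_high: np.ndarray,
    b_low: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Matched vs mismatched circular distance between two condition pairs.

    ``matched`` averages the distances d(mean A_high, mean B_high) and
    d(mean A_low, mean B_low); ``mismatched`` crosses the conditions. Standard
    errors and a two-sided p-value for matched != mismatched are obtained by
    resampling trials with replacement within each set.
    """
    import warnings

    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap estimates will be unstable")
    sets = [np.asarray(s, dtype=float) for s in (a_high, a_low, b_high, b_low)]
    if any(s.size == 0 for s in sets):
        raise ConfigurationError("all four phase sets must be non-empty")
    rng = np.random.default_rng(seed)

    def stat(ss):
        matched = 0.5 * (_mean_angle_distance(ss[0], ss[2])
                         + _mean_angle_distance(ss[1], ss[3]))
        mismatched = 0.5 * (_mean_angle_distance(ss[0], ss[3])
                            + _mean_angle_distance(ss[1], ss[2]))
        return matched, mismatched

    obs_matched, obs_mismatched = stat(sets)
    boots = np.empty((n_boot, 2))
    for k in range(n_boot):
        resampled = [s[rng.integers(0, s.size, s.size)] for s in sets]
        boots[k] = stat(resampled)
    diff = boots[:, 0] - boots[:, 1]
    p_ge = np.mean(diff >= 0)
    p_le = np.mean(diff <= 0)
    p = min(1.0, 2 * min(p_ge, p_le))
    return {
        "matched": obs_matched,
        "mismatched": obs_mismatched,
        "matched_se": float(boots[:, 0].std(ddof=1)),
        "mismatched_se": float(boots[:, 1].std(ddof=1)),
        "p_two_sided": float(max(p, 1.0 / n_boot)),
    }


def detrend_ratings_by_delay(ratings: np.ndarray, delays: np.ndarray):
    """Residual agency ratings after regressing out the go-cue-to-movement delay.

    A straight line of rating on delay is fit by least squares within the
    participant; the residuals are returned. Constant delays (degenerate fit)
    yield mean-centred ratings with ``degenerate=True``.
    """
    ratings = np.asarray(ratings, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if ratings.size < 3:
        raise ConfigurationError("need >= 3 trials to detrend")
    if np.ptp(delays) == 0:
        return ratings - ratings.mean(), True
    slope, intercept = np.polyfit(delays, ratings, 1)
    return ratings - (slope * delays + intercept), False
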