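"""Label-shuffling nulls, p-maps and cluster-based family-wise correction.

The null distribution of the phase opposition product has no known analytic
form, so inference proceeds by shuffling the condition labels (preserving
group sizes), recomputing the statistic map for each shuffle, and counting.
One-sided p-values are add-one smoothed:

    p(f, t) = (1 + #{perm : stat_perm >= stat_obs}) / (1 + n_perm)

For family-wise correction, each permutation's map is itself converted to
p-values against the full set of permutations, p is mapped to a T score by
the one-sided standard-normal quantile, supra-threshold (default T >= 2,
p ~ 0.05) connected components are scored by their T-sum, and a cluster's
corrected p is the fraction of permutations whose *maximal* cluster score
reaches the observed score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats

from .containers import AnalyticMap, ConfigurationError, LabelSet

__all__ = [
    "PermutationResult",
    "ClusterResult",
    "pop_stat",
    "permutation_pvalues",
    "cluster_correct",
    "group_pop_test",
    "power_contrast",
]


@dataclass
class PermutationResult:
    observed: np.ndarray  # (n_freqs, n_times)
    nulls: np.ndarray  # (n_perm, n_freqs, n_times)
    p: np.ndarray  # (n_freqs, n_times), add-one smoothed, one-sided
    n_perm: int
    seed: int
    freqs: np.ndarray = None
    times: np.ndarray = None


@dataclass
class ClusterResult:
    masks: list  # boolean masks on the full (n_freqs, n_times) grid
    scores: np.ndarray  # cluster T-sums
    p_values: np.ndarray  # corrected p per cluster
    threshold: float
    n_perm: int
    window_mask: np.ndarray = None  # time-axis mask actually analysed

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.p_values <= 0.05))


def _unit_phases(analytic: AnalyticMap, labels: LabelSet, channel: int):
    used = labels.labels >= 0
    v = analytic.values[used, channel]
    mag = np.abs(v)
    if np.any(mag == 0):
        raise ValueError("zero-amplitude analytic value: phase undefined")
    return v / mag, labels.labels[used] == 1


def pop_stat(unit_vectors: np.ndarray, high_mask: np.ndarray) -> np.ndarray:
    """POP map from unit phase vectors (trial axis first)."""
    u = unit_vectors
    h = np.asarray(high_mask, bool)
    n_a, n_b = h.sum(), (~h).sum()
    itc_all = np.abs(u.mean(axis=0))
    itc_a = np.abs(u[h].mean(axis=0))
    itc_b = np.abs(u[~h].mean(axis=0))
    return itc_a * itc_b - itc_all**2


def _pop_stat_batch(u: np.ndarray, high_masks: np.ndarray) -> np.ndarray:
    """Vectorised POP over many label shuffles (matmul over the trial axis)."""
    n = u.shape[0]
    shape = u.shape[1:]
    u_flat = u.reshape(n, -1)
    total = u_flat.sum(axis=0)
    n_a = int(high_masks[0].sum())
    n_b = n - n_a
    sums_a = high_masks.astype(float) @ u_flat  # (n_perm, M)
    itc_a = np.abs(sums_a) / n_a
    itc_b = np.abs(total[None, :] - sums_a) / n_b
    itc_all = np.abs(total) / n
    out = itc_a * itc_b - (itc_all**2)[None, :]
    return out.reshape((high_masks.shape[0],) + shape)


pop_stat.batch = _pop_stat_batch


def permutation_pvalues(
    stat_fn,
    analytic: AnalyticMap,
    labels: LabelSet,
    n_perm: int = 10000,
    seed: int = 0,
    channel: int = 0,
) -> PermutationResult:
    """One-sided permutation p-map for a trial-label statistic.

    ``stat_fn(unit_vectors, high_mask) -> map`` is evaluated on the observed
    labels and on ``n_perm`` label shuffles that preserve the condition sizes.
    A ``stat_fn.batch(unit_vectors, high_mask_matrix)`` attribute, if present,
    computes all shuffles at once (used by the built-in POP statistic).
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    u, high = _unit_phases(analytic, labels, channel)
    n = u.shape[0]
    rng = np.random.default_rng(seed)
    observed = stat_fn(u, high)

    perms = np.empty((n_perm, n), dtype=bool)
    for k in range(n_perm):
        perms[k] = rng.permutation(high)

    batch = getattr(stat_fn, "batch", None)
    if batch is not None:
        nulls = batch(u, perms)
    else:
        nulls = np.empty((n_perm,) + observed.shape)
        for k in range(n_perm):
            try:
                nulls[k] = stat_fn(u, perms[k])
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"statistic failed on permutation {k}: {exc}"
                ) from exc

    p = (1 + np.sum(nulls >= observed[None], axis=0)) / (1 + n_perm)
    return PermutationResult(
        observed=observed, nulls=nulls, p=p, n_perm=n_perm, seed=seed,
        freqs=analytic.freqs, times=analytic.times,
    )


def _null_pvalues(nulls: np.ndarray) -> np.ndarray:
    """p-map for every permutation against the whole permutation set."""
    n_perm = nulls.shape[0]
    flat = nulls.reshape(n_perm, -1)
    # count of permutations (including self) with value >= own value
    ranks = scipy.stats.rankdata(flat, method="min", axis=0)
    count_ge = n_perm - ranks + 1
    return (count_ge / (n_perm + 1)).reshape(nulls.shape)


def _max_cluster_score(t_map: np.ndarray, threshold: float) -> float:
    lab, n_lab = scipy.ndimage.label(t_map >= threshold)
    if n_lab == 0:
        return 0.0
    return float(max(scipy.ndimage.sum_labels(t_map, lab, range(1, n_lab + 1))))


def cluster_correct(
    perm_result: PermutationResult,
    threshold_T: float = 2.0,
    window: tuple | None = (-0.5, 0.0),
) -> ClusterResult:
    """Cluster-based family-wise correction of a permutation p-map.

    ``window`` restricts the time axis (closed-open, seconds relative to
    movement onset); clusters are 4-connected components over the
    (frequency, time) grid. An empty supra-threshold set yields an empty
    result, not an error.
    """
    times = perm_result.times
    if window is not None:
        if times is None:
            raise ConfigurationError("permutation result carries no time axis")
        tmask = (times >= window[0]) & (times < window[1])
        if not tmask.any():
            raise ConfigurationError("window contains no samples")
    else:
        tmask = np.ones(perm_result.observed.shape[-1], dtype=bool)

    obs_p = perm_result.p[:, tmask]
    nulls = perm_result.nulls[:, :, tmask]
    n_perm = perm_result.n_perm

    t_obs = scipy.stats.norm.isf(obs_p)
    null_p = _null_pvalues(nulls)
    t_null = scipy.stats.norm.isf(null_p)

    null_max = np.array(
        [_max_cluster_score(t_null[k], threshold_T) for k in range(n_perm)]
    )

    lab, n_lab = scipy.ndimage.label(t_obs >= threshold_T)
    masks, scores, pvals = [], [], []
    full_shape = perm_result.observed.shape
    t_idx = np.flatnonzero(tmask)
    for c in range(1, n_lab + 1):
        m_w = lab == c
        score = float(t_obs[m_w].sum())
        p = (1 + np.sum(null_max >= score)) / (1 + n_perm)
        full_mask = np.zeros(full_shape, dtype=bool)
        full_mask[:, t_idx] = m_w
        masks.append(full_mask)
        scores.append(score)
        pvals.append(p)
    order = np.argsort(pvals) if pvals else []
    return ClusterResult(
        masks=[masks[i] for i in order],
        scores=np.array([scores[i] for i in order]),
        p_values=np.array([pvals[i] for i in order]),
        threshold=threshold_T,
        n_perm=n_perm,
        window_mask=tmask,
    )


def group_pop_test(
    observed_maps: list,
    null_maps: list,
    freqs: np.ndarray,
    times: np.ndarray,
    band: tuple = (8.0, 13.0),
    window: tuple = (-0.5, 0.0),
) -> dict:
    """Group-level POP test by averaging subject POP maps over a window.

    Labels are shuffled within each subject (the per-subject null maps);
    the group statistic is the subject-mean POP averaged over the declared
    frequency band and time window, and the p-value counts permutations with
    a larger permuted group mean. Subjects with missing nulls are excluded
    with a warning.
    """
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    tmask = (times >= window[0]) & (times < window[1])
    if not tmask.any():
        raise ConfigurationError("empty analysis window")

    obs_vals, null_vals = [], []
    for i, (o, nl) in enumerate(zip(observed_maps, null_maps)):
        if nl is None:
            warnings.warn(f"subject {i} has no null maps; excluded")
            continue
        obs_vals.append(o[fmask][:, tmask].mean())
        null_vals.append(nl[:, fmask][:, :, tmask].mean(axis=(1, 2)))
    if not obs_vals:
        raise ConfigurationError("no usable subjects")
    null_vals = np.asarray(null_vals)  # (n_subjects, n_perm)
    if len({v.size for v in null_vals}) > 1:  # pragma: no cover
        raise ConfigurationError("permutation counts differ across subjects")
    group_obs = float(np.mean(obs_vals))
    group_null = null_vals.mean(axis=0)
    n_perm = group_null.size
    p = (1 + np.sum(group_null >= group_obs)) / (1 + n_perm)
    return {
        "group_pop": group_obs,
        "p": float(p),
        "n_subjects": len(obs_vals),
        "n_perm": int(n_perm),
    }


def _t_map_two_sample(power: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Two-sample t per (f, t) on instantaneous power (equal-variance)."""
    a, b = power[high], power[~high]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)  # zero-variance points flagged as 0


def power_contrast(
    analytic: AnalyticMap,
    labels: LabelSet,
    window: tuple | None = (-0.5, 0.0),
    n_perm: int = 1000,
    seed: int = 0,
    threshold_T: float = 2.0,
    channel: int = 0,
) -> tuple[np.ndarray, ClusterResult]:
    """Cluster-corrected two-sample t contrast of instantaneous power.

    Power is the squared magnitude of the analytic values. The point-level
    statistic is |t| (two-sided); the null is obtained by label permutation
    and maximal-cluster scoring, mirroring the POP correction.
    """
    used = labels.labels >= 0
    power = np.abs(analytic.values[used, channel]) ** 2
    high = labels.labels[used] == 1
    if high.sum() < 2 or (~high).sum() < 2:
        raise ConfigurationError("need >= 2 trials per condition")

    times = analytic.times
    if window is not None:
        tmask = (times >= window[0]) & (times < window[1])
        power_w = power[:, :, tmask]
    else:
        tmask = np.ones(power.shape[-1], dtype=bool)
        power_w = power

    t_obs = _t_map_two_sample(power_w, high)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        hp = rng.permutation(high)
        null_max[k] = _max_cluster_score(
            np.abs(_t_map_two_sample(power_w, hp)), threshold_T
        )

    lab, n_lab = scipy.ndimage.label(np.abs(t_obs) >= threshold_T)
    masks, scores, pvals = [], [], []
    t_idx = np.flatnonzero(tmask)
    for c in range(1, n_lab + 1):
        m_w = lab == c
        score = float(np.abs(t_obs)[m_w].sum())
        p = (1 + np.sum(null_max >= score)) / (1 + n_perm)
        full = np.zeros((power.shape[1], power.shape[2]), dtype=bool)
        full[:, t_idx] = m_w
        masks.append(full)
        scores.append(score)
        pvals.append(p)
    order = np.argsort(pvals) if pvals else []
    t_full = np.zeros((power.shape[1], power.shape[2]))
    t_full[:, t_idx] = t_obs
    return t_full, ClusterResult(
        masks=[masks[i] for i in order],
        scores=np.array([scores[i] for i in order]),
        p_values=np.array([pvals[i] for i in order]),
        threshold=threshold_T,
        n_perm=n_perm,
        window_mask=tmask,
    )
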