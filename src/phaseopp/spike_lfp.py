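"""Spike-field coupling statistics.

The phase-locking value (PLV) between spiking and a field oscillation is the
inter-trial coherence of oscillation phase angles sampled at spike times:
``PLV(f) = |sum_k exp(i phi_k)| / K`` over all pooled spikes. A flat spike-
phase distribution gives PLV -> 0; spikes locked to one phase give PLV = 1.
Five equal phase bins aligned to the global preferred phase summarise the
modulation as relative spike probabilities (1/5 = 0.2 each under the null).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .containers import AnalyticMap, ConfigurationError, LabelSet, SpikeTrainSet

__all__ = [
    "phases_at_spikes",
    "spike_field_plv",
    "spike_phase_histogram",
    "unit_preferred_angles",
    "firing_rate_contrast",
    "plv_contrast_by_label",
]


def phases_at_spikes(
    analytic: AnalyticMap,
    spikes: SpikeTrainSet,
    freq: float,
    channel: int = 0,
) -> pd.DataFrame:
    """Oscillation phase at each spike, at one analytic frequency.

    Spikes map to the nearest sample (ties toward the earlier sample); spikes
    falling on edge-invalid samples are dropped, with the count recorded in
    the returned frame's ``attrs["n_dropped"]``.
    """
    fi = analytic.freq_index(freq)
    fs = analytic._fs()
    t0 = analytic.times[0]
    ev = spikes.events
    idx = np.ceil((ev["time_s"].to_numpy() - t0) * fs - 0.5).astype(int)
    in_range = (idx >= 0) & (idx < analytic.times.size)
    valid = np.zeros(ev.shape[0], dtype=bool)
    valid[in_range] = analytic.valid[fi, idx[in_range]]
    n_dropped = int((~valid).sum())

    trials = ev["trial"].to_numpy()[valid]
    units = ev["unit"].to_numpy()[valid]
    vals = analytic.values[trials, channel, fi, idx[valid]]
    phases = np.angle(vals)
    if phases.size == 0:
        raise ConfigurationError("no valid spikes at this frequency")
    out = pd.DataFrame({"unit": units, "trial": trials, "phase": phases})
    out.attrs["n_dropped"] = n_dropped
    out.attrs["freq"] = float(freq)
    return out


def spike_field_plv(phases: np.ndarray) -> float:
    """PLV of pooled spike phases: resultant length of unit phase vectors."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ConfigurationError("no spikes")
    if phases.size < 50:
        warnings.warn("fewer than 50 spikes: PLV estimate is noisy")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def spike_phase_histogram(
    phases: np.ndarray,
    n_bins: int = 5,
    reference: float = 0.0,
    ci_level: float = 0.66,
) -> dict:
    """Relative spike probability in equal phase bins aligned to a reference.

    Bins have width 2*pi/n_bins; bin 0 is centred on the global preferred
    phase ``reference``. Probabilities sum to 1 exactly. Confidence intervals
    are normal-approximation binomial at ``ci_level`` (default 66%).
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    phases = np.asarray(phases, dtype=float)
    width = 2 * np.pi / n_bins
    # shift so bin 0 is centred on the reference
    rel = np.mod(phases - reference + width / 2, 2 * np.pi)
    idx = np.minimum((rel // width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    k = phases.size
    prob = counts / k
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2)
    se = np.sqrt(prob * (1 - prob) / k)
    centres = reference + width * np.arange(n_bins)
    return {
        "bin_centres": np.angle(np.exp(1j * centres)),
        "probability": prob,
        "count": counts,
        "ci_low": prob - z * se,
        "ci_high": prob + z * se,
    }


def unit_preferred_angles(
    phase_table: pd.DataFrame, min_spikes: int = 10
) -> pd.DataFrame:
    """Per-unit preferred angle and resultant length of spike-phase vectors.

    Units with fewer than ``min_spikes`` spikes are kept but flagged
    (``reliable = False``): their angles are uninformative.
    """
    rows = []
    for unit, grp in phase_table.groupby("unit"):
        r = np.mean(np.exp(1j * grp["phase"].to_numpy()))
        rows.append(
            {
                "unit": unit,
                "preferred_angle": float(np.angle(r)),
                "resultant_length": float(np.abs(r)),
                "n_spikes": len(grp),
                "reliable": len(grp) >= min_spikes,
            }
        )
    return pd.DataFrame(rows)


def firing_rate_contrast(
    spikes: SpikeTrainSet,
    labels: LabelSet,
    epoch: tuple,
    bin_width: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    threshold_T: float = 2.0,
) -> dict:
    """Trial-averaged firing-rate curves per condition with a cluster test.

    All units are pooled per trial; rates are spikes per second per trial in
    ``bin_width`` bins over ``epoch`` (empty bins count as rate 0). The two
    conditions are compared pointwise by t-statistic with label-permutation
    maximal-cluster correction over time bins.
    """
    if not (labels.high_mask.any() and labels.low_mask.any()):
        raise ConfigurationError("both conditions must be non-empty")
    edges = np.arange(epoch[0], epoch[1] + bin_width / 2, bin_width)
    n_bins = edges.size - 1
    n_trials = labels.n_trials
    counts = np.zeros((n_trials, n_bins))
    ev = spikes.events
    for trial, grp in ev.groupby("trial"):
        h, _ = np.histogram(grp["time_s"].to_numpy(), bins=edges)
        counts[int(trial)] = h
    rates = counts / bin_width

    high = labels.high_mask
    used = labels.labels >= 0
    rates_u, high_u = rates[used], high[used]

    def tstat(h):
        a, b = rates_u[h], rates_u[~h]
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va = a.var(axis=0, ddof=1) / a.shape[0]
        vb = b.var(axis=0, ddof=1) / b.shape[0]
        denom = np.sqrt(va + vb)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (ma - mb) / denom
        return np.where(denom == 0, 0.0, t)

    t_obs = tstat(high_u)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        hp = rng.permutation(high_u)
        tm = np.abs(tstat(hp))
        lab, n_lab = scipy.ndimage.label(tm >= threshold_T)
        null_max[k] = (
            max(scipy.ndimage.sum_labels(tm, lab, range(1, n_lab + 1)))
            if n_lab
            else 0.0
        )

    lab, n_lab = scipy.ndimage.label(np.abs(t_obs) >= threshold_T)
    clusters = []
    for c in range(1, n_lab + 1):
        m = lab == c
        score = float(np.abs(t_obs)[m].sum())
        p = (1 + np.sum(null_max >= score)) / (1 + n_perm)
        clusters.append({"mask": m, "score": score, "p": float(p)})

    def curve(mask):
        r = rates_u[mask]
        return r.mean(axis=0), r.std(axis=0, ddof=1) / np.sqrt(r.shape[0])

    mean_high, sem_high = curve(high_u)
    mean_low, sem_low = curve(~high_u)
    return {
        "bin_centres": 0.5 * (edges[:-1] + edges[1:]),
        "rate_high": mean_high,
        "sem_high": sem_high,
        "rate_low": mean_low,
        "sem_low": sem_low,
        "t": t_obs,
        "clusters": clusters,
    }


def plv_contrast_by_label(
    phases_a: np.ndarray,
    phases_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """PLV difference between two spike groups with a permutation null.

    ``delta = PLV(A) - PLV(B)``; the null shuffles spike group membership.
    Relabelling the groups flips the sign of delta exactly.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both spike groups must be non-empty")
    if min(a.size, b.size) < 50:
        warnings.warn("fewer than 50 spikes in a group: contrast is noisy")
    pooled = np.concatenate([a, b])
    na = a.size

    def delta(ph_a, ph_b):
        return float(
            np.abs(np.mean(np.exp(1j * ph_a))) - np.abs(np.mean(np.exp(1j * ph_b)))
        )

    obs = delta(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = delta(perm[:na], perm[na:])
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (1 + n_perm)
    return {"delta_plv": obs, "p": float(p), "n_perm": n_perm}
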