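"""Phase-conditioned functional connectivity and directionality.

Connectivity uses the debiased weighted phase-lag index (dWPLI), an estimator
built on the imaginary part of the cross-spectrum: it discounts zero-lag
(volume-conduction-like) coupling by construction and removes the positive
small-sample bias of the squared WPLI. With imaginary cross-spectrum
observations y_j pooled over trials and window samples,

    dWPLI = ( (sum y)^2 - sum y^2 ) / ( (sum |y|)^2 - sum y^2 ).

Directionality is assessed by lagged phase coherence: the inter-trial
coherence of the seed-target phase difference as a function of an imposed
delay on the target. A peak at a positive lag means the seed's present best
predicts the target's future, i.e. the seed leads.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.ndimage
import scipy.stats

from .containers import AnalyticMap, ConfigurationError, PhasePartition

__all__ = [
    "CONNECTIVITY_FREQS",
    "DIRECTIONALITY_FREQS",
    "debiased_wpli",
    "wpli_contrast_for_subject",
    "phase_split_connectivity_contrast",
    "lag_phase_coherence",
    "directionality_shift_test",
    "paired_t",
]

CONNECTIVITY_FREQS = np.linspace(4.0, 45.0, 42)
DIRECTIONALITY_FREQS = np.array([9.0, 10.0, 11.0, 12.0])
DEFAULT_WINDOW = (0.2, 1.2)  # s post-movement, onset to behavioural response


def debiased_wpli(
    analytic: AnalyticMap,
    ch_x: int,
    ch_y: int,
    trials: np.ndarray | None = None,
    window: tuple = DEFAULT_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Debiased WPLI spectrum between two channels.

    Observations are cross-spectral samples pooled over the selected trials
    and the analysis window. Returns ``(wpli, degenerate)`` per frequency;
    degenerate frequencies (all imaginary parts zero, e.g. an exact zero-lag
    copy) are reported as 0 with the flag set.
    """
    if trials is None:
        trials = np.arange(analytic.values.shape[0])
    trials = np.asarray(trials)
    if trials.size < 2:
        raise ConfigurationError("dWPLI undefined for a single trial")
    if trials.size < 10:
        warnings.warn("fewer than 10 trials: dWPLI estimate is unstable")
    tmask = (analytic.times >= window[0]) & (analytic.times < window[1])
    tmask &= analytic.valid.all(axis=0)
    if not tmask.any():
        raise ConfigurationError("analysis window contains no valid samples")

    x = analytic.values[trials][:, ch_x][:, :, tmask]
    y = analytic.values[trials][:, ch_y][:, :, tmask]
    cross = x * np.conj(y)  # (n_trials, n_freqs, n_samples)
    im = np.moveaxis(np.imag(cross), 1, 0).reshape(cross.shape[1], -1)
    mag = np.moveaxis(np.abs(cross), 1, 0).reshape(cross.shape[1], -1)

    s = im.sum(axis=1)
    ssq = (im**2).sum(axis=1)
    sabs = np.abs(im).sum(axis=1)
    num = s**2 - ssq
    den = sabs**2 - ssq
    # degenerate when the imaginary parts vanish relative to the
    # cross-spectrum magnitude (exact zero-lag mixing up to rounding)
    scale = mag.sum(axis=1) ** 2
    degenerate = den <= 1e-20 * scale
    wpli = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return wpli, degenerate


def wpli_contrast_for_subject(
    analytic: AnalyticMap,
    partition: PhasePartition,
    seed_channel: int,
    targets: list,
    window: tuple = DEFAULT_WINDOW,
) -> dict:
    """Optimal-minus-non-optimal dWPLI spectra from a seed to each target.

    Returns per-target delta spectra and their mean across targets.
    """
    if min(partition.optimal.size, partition.non_optimal.size) < 2:
        raise ConfigurationError("both partition groups need >= 2 trials")
    deltas = {}
    for tgt in targets:
        w_opt, _ = debiased_wpli(
            analytic, seed_channel, tgt, partition.optimal, window
        )
        w_non, _ = debiased_wpli(
            analytic, seed_channel, tgt, partition.non_optimal, window
        )
        deltas[tgt] = w_opt - w_non
    mean_delta = np.mean(np.stack(list(deltas.values())), axis=0)
    return {"per_target": deltas, "mean": mean_delta}


def paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Paired t statistic and two-sided p, implemented from the definition.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with n-1 degrees of freedom.
    """
    d = np.asarray(diff, dtype=float)
    n = d.size
    if n < 2:
        raise ConfigurationError("paired t needs >= 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if d.mean() == 0 else (np.inf, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def _max_cluster_1d(stat: np.ndarray, threshold: float) -> float:
    lab, n_lab = scipy.ndimage.label(stat >= threshold)
    if n_lab == 0:
        return 0.0
    return float(max(scipy.ndimage.sum_labels(stat, lab, range(1, n_lab + 1))))


def phase_split_connectivity_contrast(
    subject_deltas: list,
    freqs: np.ndarray,
    per_target_deltas: list | None = None,
    macro_groups: dict | None = None,
    band: tuple = (9.0, 12.0),
    n_perm: int = 1000,
    seed: int = 0,
    threshold_T: float = 2.0,
) -> dict:
    """Group-level contrast of phase-split connectivity.

    ``subject_deltas`` holds one optimal-minus-non-optimal dWPLI spectrum per
    subject (seed to targets, already averaged over targets). The paired
    comparison across subjects is run per frequency; multiplicity across
    frequencies is handled by a sign-flip maximal-cluster permutation test on
    |t| >= threshold. If ``macro_groups`` maps group names to target ids and
    ``per_target_deltas`` gives each subject's per-target spectra, the
    band-averaged contrast is additionally tested per macro group with
    Bonferroni correction across groups.

    The contrast is antisymmetric under swapping optimal and non-optimal.
    """
    deltas = np.asarray(subject_deltas, dtype=float)  # (n_subj, n_freqs)
    n_subj = deltas.shape[0]
    if n_subj < 3:
        raise ConfigurationError("need >= 3 subjects for the paired contrast")

    def tvec(d):
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = d.mean(axis=0) / (sd / np.sqrt(d.shape[0]))
        return np.where(sd == 0, 0.0, t)

    t_obs = tvec(deltas)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        null_max[k] = _max_cluster_1d(np.abs(tvec(deltas * flips[:, None])),
                                      threshold_T)

    lab, n_lab = scipy.ndimage.label(np.abs(t_obs) >= threshold_T)
    clusters = []
    for c in range(1, n_lab + 1):
        m = lab == c
        score = float(np.abs(t_obs)[m].sum())
        p = (1 + np.sum(null_max >= score)) / (1 + n_perm)
        clusters.append(
            {"mask": m, "freqs": freqs[m], "score": score, "p": float(p)}
        )
    clusters.sort(key=lambda c: c["p"])

    groups_out = None
    if macro_groups is not None:
        if per_target_deltas is None:
            raise ConfigurationError("macro groups need per-target deltas")
        fmask = (freqs >= band[0]) & (freqs <= band[1])
        groups_out = {}
        n_groups = len(macro_groups)
        for name, members in macro_groups.items():
            vals = []
            for subj in per_target_deltas:
                member_specs = [subj[m] for m in members]
                vals.append(np.mean(np.stack(member_specs)[:, fmask]))
            t, p = paired_t(np.asarray(vals))
            groups_out[name] = {
                "t": t,
                "p": p,
                "p_bonferroni": min(1.0, p * n_groups),
                "mean_delta": float(np.mean(vals)),
            }

    return {"t": t_obs, "clusters": clusters, "macro_groups": groups_out}


def lag_phase_coherence(
    analytic: AnalyticMap,
    seed_channel: int,
    target_channel: int,
    lags: np.ndarray | None = None,
    freqs: np.ndarray = DIRECTIONALITY_FREQS,
    window: tuple = DEFAULT_WINDOW,
    trials: np.ndarray | None = None,
) -> dict:
    """Inter-trial coherence of seed-target phase differences versus lag.

    For each lag L (positive = target delayed) the phase difference
    ``phi_seed(t) - phi_target(t + L)`` is formed per trial and window sample;
    the ITC is taken across trials at each (frequency, sample) and then
    averaged over window samples and frequencies, leaving a curve over lags.
    The peak lag is the argmax, ties broken toward 0; a flat curve yields
    ``peak_lag = None``.
    """
    fs = analytic._fs()
    if lags is None:
        lags = np.arange(-20, 21) * 0.005  # +-100 ms in 5 ms steps, exact 0
    lags = np.asarray(lags, dtype=float)
    lag_samps = np.round(lags * fs).astype(int)
    if trials is None:
        trials = np.arange(analytic.values.shape[0])

    fidx = [analytic.freq_index(f) for f in freqs]
    tmask = (analytic.times >= window[0]) & (analytic.times < window[1])
    tmask &= analytic.valid[fidx].all(axis=0)
    t_idx = np.flatnonzero(tmask)
    n_t = analytic.times.size
    if t_idx.size == 0:
        raise ConfigurationError("window contains no valid samples")
    if t_idx[0] + lag_samps.min() < 0 or t_idx[-1] + lag_samps.max() >= n_t:
        raise ConfigurationError("lag range exceeds the epoch margin")

    sv = analytic.values[trials][:, seed_channel][:, fidx]  # (n_tr, n_f, n_t)
    tv = analytic.values[trials][:, target_channel][:, fidx]
    s_ph = sv[:, :, t_idx] / np.abs(sv[:, :, t_idx])

    coh = np.empty(lags.size)
    for j, ls in enumerate(lag_samps):
        t_shift = tv[:, :, t_idx + ls]
        d = s_ph * np.conj(t_shift / np.abs(t_shift))
        itc = np.abs(d.mean(axis=0))  # ITC across trials, per (freq, sample)
        coh[j] = itc.mean()

    if np.ptp(coh) < 1e-12:
        peak = None
    else:
        best = coh.max()
        cand = np.flatnonzero(coh == best)
        # ties toward zero lag, then toward the negative side (deterministic)
        cand = sorted(cand, key=lambda i: (abs(lags[i]), lags[i]))
        peak = float(lags[cand[0]])
    return {"lags": lags, "coherence": coh, "peak_lag": peak}


def directionality_shift_test(
    peak_lags_optimal: np.ndarray,
    peak_lags_non_optimal: np.ndarray,
) -> dict:
    """Paired comparison of per-subject peak lags between phase partitions.

    Subjects with an undefined peak (flat curve, NaN) are excluded with a
    warning. Positive differences indicate the seed leads more strongly on
    optimal-phase trials.
    """
    a = np.asarray(peak_lags_optimal, dtype=float)
    b = np.asarray(peak_lags_non_optimal, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} subject(s) with flat curves excluded")
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ConfigurationError("need >= 3 subjects with defined peaks")
    d = a - b
    t, p = paired_t(d)
    return {
        "mean_shift": float(d.mean()),
        "t": t,
        "p": p,
        "n_subjects": int(a.size),
        "per_subject_shift": d,
    }
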