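"""End-to-end workflows chaining the analysis stages.

Each workflow consumes a trial container (synthetic or user-supplied),
runs the spectral extraction, the statistic of interest and its permutation
inference, and returns a JSON-serialisable report embedding the full run
configuration and all seeds. Numeric tables are written as CSV with nine
significant digits so identical runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha_peak as ap
from . import connectivity as conn
from . import phase_stats as ps
from . import permutation as perm
from . import spectral
from .containers import ConfigurationError, LabelSet, TrialSet

__all__ = ["RunConfig", "run_pop_workflow", "run_connectivity_workflow"]

_FLOAT_FMT = "%.9g"


@dataclass
class RunConfig:
    """Configuration shared by the workflows."""

    freqs: tuple = tuple(spectral.DEFAULT_LFP_FREQS)
    n_cycles: float = spectral.DEFAULT_N_CYCLES
    causal_band: tuple = (6.0, 10.0)
    cluster_window: tuple = (-0.5, 0.0)
    n_perm: int = 1000
    seed: int = 0
    threshold_T: float = 2.0
    band: tuple = (8.0, 13.0)
    lag_max: float = 0.100
    lag_step: float = 0.005
    connectivity_window: tuple = conn.DEFAULT_WINDOW
    out_dir: str | None = None


def _split_extremes(labels: LabelSet, fraction: float = 1 / 3) -> LabelSet:
    """Label the highest/lowest third of delay-detrended ratings, excluding
    the uninformative middle."""
    residuals, _ = ps.detrend_ratings_by_delay(labels.ratings, labels.delays)
    n = residuals.size
    k = int(round(fraction * n))
    order = np.argsort(residuals, kind="stable")
    new = np.full(n, -1, dtype=int)
    new[order[:k]] = 0
    new[order[-k:]] = 1
    return LabelSet(labels=new, ratings=labels.ratings, delays=labels.delays)


def run_pop_workflow(
    trials: TrialSet, labels: LabelSet, config: RunConfig | None = None
) -> dict:
    """Phase-opposition workflow for a single subject.

    Rating-style labels (raw 1-9 ratings with delays) are first detrended and
    split into extreme thirds. Both the Morlet and the causal-filter analytic
    routes are run; inference (permutation p-map, cluster correction) uses
    the Morlet route. The optimal phase angle and a phase-binned outcome
    probability are computed at the point of strongest opposition.
    """
    cfg = config or RunConfig()
    if labels.ratings is not None and labels.delays is not None:
        labels = _split_extremes(labels)
    n_a = int((labels.labels == 1).sum())
    n_b = int((labels.labels == 0).sum())
    if min(n_a, n_b) < 2:
        raise ConfigurationError("insufficient trials per condition")

    analytic = spectral.morlet_analytic(
        trials, np.asarray(cfg.freqs), n_cycles=cfg.n_cycles
    )
    pr = perm.permutation_pvalues(
        perm.pop_stat, analytic, labels, n_perm=cfg.n_perm, seed=cfg.seed
    )
    clusters = perm.cluster_correct(
        pr, threshold_T=cfg.threshold_T, window=cfg.cluster_window
    )

    # point of strongest opposition within the window
    tmask = (analytic.times >= cfg.cluster_window[0]) & (
        analytic.times < cfg.cluster_window[1]
    )
    p_win = np.where(tmask[None, :], pr.p, np.inf)
    min_p = p_win.min()
    # ties at the attainable minimum resolved by the strongest observed POP
    cand = np.where(p_win == min_p, pr.observed, -np.inf)
    fi, ti = np.unravel_index(np.argmax(cand), cand.shape)
    used = labels.labels >= 0
    point_phases = np.angle(analytic.values[used, 0, fi, ti])
    high = labels.labels[used] == 1
    opt_angle = ps.optimal_phase_angle(point_phases[high], point_phases[~high])
    partition = ps.select_phase_trials(point_phases, opt_angle)
    binned = ps.phase_binned_outcome_probability(
        point_phases, high.astype(int), n_bins=6, reference_angle=opt_angle
    )

    causal = spectral.causal_analytic(trials, cfg.causal_band)
    causal_pr = perm.permutation_pvalues(
        perm.pop_stat, causal, labels, n_perm=cfg.n_perm, seed=cfg.seed
    )
    causal_min_p = float(
        np.min(
            np.where(
                ((causal.times >= cfg.cluster_window[0])
                 & (causal.times < cfg.cluster_window[1])
                 & causal.valid[0])[None, :],
                causal_pr.p,
                np.inf,
            )
        )
    )

    report = {
        "config": asdict(cfg),
        "n_trials": {"high": n_a, "low": n_b},
        "clusters": [
            {"score": float(s), "p": float(p)}
            for s, p in zip(clusters.scores, clusters.p_values)
        ],
        "n_significant_clusters": clusters.n_significant,
        "best_point": {
            "frequency_hz": float(analytic.freqs[fi]),
            "time_s": float(analytic.times[ti]),
            "p": float(pr.p[fi, ti]),
            "pop": float(pr.observed[fi, ti]),
        },
        "optimal_angle_rad": float(opt_angle),
        "partition": {
            "n_optimal": int(partition.optimal.size),
            "n_non_optimal": int(partition.non_optimal.size),
        },
        "phase_binned_probability": {
            "bin_centres": binned["bin_centres"].tolist(),
            "probability": binned["probability"].tolist(),
        },
        "causal_control_min_p": causal_min_p,
        "seed": cfg.seed,
    }
    if cfg.out_dir is not None:
        _write_pop_outputs(Path(cfg.out_dir), report, pr, clusters)
    report["_perm_result"] = pr
    report["_clusters"] = clusters
    return report


def _write_pop_outputs(out_dir, report, pr, clusters):
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        pr.p, index=pr.freqs, columns=np.round(pr.times, 6)
    ).to_csv(out_dir / "pop_pvalues.csv", float_format=_FLOAT_FMT)
    rows = []
    for m, s, p in zip(clusters.masks, clusters.scores, clusters.p_values):
        fsel = np.flatnonzero(m.any(axis=1))
        tsel = np.flatnonzero(m.any(axis=0))
        rows.append(
            {
                "f_lo_hz": pr.freqs[fsel[0]],
                "f_hi_hz": pr.freqs[fsel[-1]],
                "t_lo_s": pr.times[tsel[0]],
                "t_hi_s": pr.times[tsel[-1]],
                "score": s,
                "p_corrected": p,
            }
        )
    pd.DataFrame(
        rows,
        columns=["f_lo_hz", "f_hi_hz", "t_lo_s", "t_hi_s", "score", "p_corrected"],
    ).to_csv(out_dir / "clusters.csv", index=False, float_format=_FLOAT_FMT)
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    (out_dir / "report.json").write_text(json.dumps(clean, indent=1))


def run_connectivity_workflow(
    subjects: list,
    seed_channel: int = 0,
    targets: list | None = None,
    macro_groups: dict | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Phase-conditioned connectivity and directionality across a cohort.

    ``subjects`` is a list of ``{"trials": TrialSet, "labels": LabelSet}``
    dicts with multichannel data. Per subject: phase-opposition inference in
    the alpha band determines the individual optimal angle; trials are split
    into optimal / non-optimal; the dWPLI contrast and the lag-ITC curves are
    computed on each partition. Subjects with no significant pre-movement
    opposition are excluded from the group statistics but listed in the
    report.
    """
    cfg = config or RunConfig()
    if targets is None:
        targets = [1]
    n_lags = int(round(cfg.lag_max / cfg.lag_step))
    lags = np.arange(-n_lags, n_lags + 1) * cfg.lag_step

    excluded, deltas, per_target, peaks_opt, peaks_non = [], [], [], [], []
    for i, subj in enumerate(subjects):
        trials, labels = subj["trials"], subj["labels"]
        analytic = spectral.morlet_analytic(
            trials, np.asarray(cfg.freqs), n_cycles=cfg.n_cycles
        )
        pr = perm.permutation_pvalues(
            perm.pop_stat, analytic, labels,
            n_perm=cfg.n_perm, seed=cfg.seed + i, channel=seed_channel,
        )
        best = ap.peak_pop_frequency(pr, window=cfg.cluster_window)
        if not best["significant"]:
            excluded.append(i)
            continue
        # individual point of strongest opposition: minimum p, ties resolved
        # by the strongest observed POP
        tmask = (analytic.times >= cfg.cluster_window[0]) & (
            analytic.times < cfg.cluster_window[1]
        )
        p_win = np.where(tmask[None, :], pr.p, np.inf)
        cand = np.where(p_win == p_win.min(), pr.observed, -np.inf)
        f_idx, t_idx = np.unravel_index(np.argmax(cand), cand.shape)
        trial_phases = np.angle(analytic.values[:, seed_channel, f_idx, t_idx])
        high = labels.labels == 1
        opt = ps.optimal_phase_angle(trial_phases[high], trial_phases[~high])
        part = ps.select_phase_trials(trial_phases, opt)
        if min(part.optimal.size, part.non_optimal.size) < 2:
            excluded.append(i)
            continue

        contrast = conn.wpli_contrast_for_subject(
            analytic, part, seed_channel, targets, window=cfg.connectivity_window
        )
        deltas.append(contrast["mean"])
        per_target.append(contrast["per_target"])
        c_opt = conn.lag_phase_coherence(
            analytic, seed_channel, targets[0], lags,
            freqs=_directionality_freqs(analytic.freqs),
            window=cfg.connectivity_window, trials=part.optimal,
        )
        c_non = conn.lag_phase_coherence(
            analytic, seed_channel, targets[0], lags,
            freqs=_directionality_freqs(analytic.freqs),
            window=cfg.connectivity_window, trials=part.non_optimal,
        )
        peaks_opt.append(np.nan if c_opt["peak_lag"] is None else c_opt["peak_lag"])
        peaks_non.append(np.nan if c_non["peak_lag"] is None else c_non["peak_lag"])

    if not deltas:
        raise ConfigurationError("all subjects excluded: no significant opposition")

    group = conn.phase_split_connectivity_contrast(
        deltas,
        np.asarray(cfg.freqs),
        per_target_deltas=per_target,
        macro_groups=macro_groups,
        band=(9.0, 12.0),
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        threshold_T=cfg.threshold_T,
    )
    shift = conn.directionality_shift_test(peaks_opt, peaks_non)
    return {
        "config": asdict(cfg),
        "excluded_subjects": excluded,
        "n_subjects_used": len(deltas),
        "contrast_clusters": [
            {"freqs": c["freqs"].tolist(), "score": c["score"], "p": c["p"]}
            for c in group["clusters"]
        ],
        "macro_groups": group["macro_groups"],
        "directionality": {
            "mean_shift_s": shift["mean_shift"],
            "t": shift["t"],
            "p": shift["p"],
            "n_subjects": shift["n_subjects"],
        },
        "seed": cfg.seed,
    }


def _directionality_freqs(grid: np.ndarray) -> np.ndarray:
    """Directionality frequencies (9-12 Hz) restricted to the analytic grid."""
    sel = [f for f in conn.DIRECTIONALITY_FREQS
           if np.any(np.abs(grid - f) < 1e-6)]
    if not sel:
        sel = [float(g) for g in grid if 9.0 <= g <= 12.0]
    if not sel:
        raise ConfigurationError("no 9-12 Hz frequencies on the analytic grid")
    return np.asarray(sel)
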