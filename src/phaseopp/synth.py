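"""Synthetic data generators with planted ground truth.

Every downstream analysis stage has a generator here that produces data with
the exact statistical structure the stage assumes:

* trials whose pre-movement oscillatory phase at a planted (frequency, time)
  point is von Mises-concentrated and opposed between two behavioural
  conditions, riding on 1/f background noise;
* trial-wise binary outcomes whose probability follows a cosine link in the
  distance from an optimal phase;
* inhomogeneous-Poisson spike trains whose rate is sinusoidally modulated by
  the planted oscillation phase;
* two-channel source pairs whose lagged-coupling direction is gated by the
  seed's pre-movement phase;
* subject cohorts with individually varying alpha-peak frequencies.

All generators draw from a single ``numpy.random.Generator`` seeded from the
config, record the seed and planted truth in the output metadata, and are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.signal

from .containers import (
    ConfigurationError,
    LabelSet,
    SpikeTrainSet,
    TrialSet,
)

__all__ = [
    "SynthTrialConfig",
    "SpikeSynthConfig",
    "CoupledPairConfig",
    "make_phase_coded_trials",
    "make_agency_labels_from_phase",
    "make_spike_trains",
    "make_coupled_source_pair",
    "make_subject_cohort",
    "one_over_f_noise",
]


@dataclass
class SynthTrialConfig:
    """Configuration for phase-coded trial generation.

    The planted effect lives at ``(f0, t_lock)``: condition A ("high") trials
    have oscillation phase ~ von Mises(mu_high, kappa) at ``t_lock``, condition
    B ("low") trials ~ von Mises(mu_high + pi, kappa). ``kappa = 0`` plants no
    effect (uniform phases in both conditions).
    """

    n_trials_per_condition: int = 100
    n_channels: int = 1
    fs: float = 250.0
    epoch: tuple = (-2.0, 1.0)  # seconds, t=0 = movement onset
    f0: float = 8.0
    t_lock: float = -0.256
    mu_high: float = 1.0
    kappa: float = 5.0
    osc_amplitude: float = 1.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        t_start, t_end = self.epoch
        if not (t_start < self.t_lock < 0 <= t_end):
            raise ConfigurationError(
                "epoch must satisfy t_start < t_lock < 0 <= t_end"
            )
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.n_trials_per_condition < 1:
            raise ConfigurationError("need at least one trial per condition")


@dataclass
class SpikeSynthConfig:
    """Sinusoidally phase-modulated Poisson spiking parameters."""

    base_rate: float = 20.0  # Hz
    mod_depth: float = 0.5  # m in [0, 1]
    preferred_phase: float = 4 * np.pi / 3
    n_units: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.base_rate < 0:
            raise ConfigurationError("base_rate must be >= 0")
        if not 0 <= self.mod_depth <= 1:
            raise ConfigurationError("mod_depth must be in [0, 1]")


@dataclass
class CoupledPairConfig:
    """Phase-gated, lagged coupling between a seed and a target source.

    On trials whose seed phase at ``t_lock`` is within pi/3 of ``gate_phase``
    the target receives a lagged copy of the seed (seed leads); on the other
    trials the coupling direction is reversed.
    """

    band: tuple = (9.0, 12.0)  # Hz; centre frequency drives the oscillation
    coupling_lag: float = 0.030  # s, > 0
    coupling_gain: float = 0.9
    gate_phase: float = 0.0
    fs: float = 200.0
    epoch: tuple = (-1.5, 1.5)
    t_lock: float = -0.256
    noise_amplitude: float = 0.3
    osc_amplitude: float = 1.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (0 < self.coupling_lag < 1.0 / f_lo):
            raise ConfigurationError("coupling_lag must be in (0, 1/f_lo)")
        if not 0 <= self.coupling_gain <= 1:
            raise ConfigurationError("coupling_gain must be in [0, 1]")
        if self.coupling_lag >= self.epoch[1] - self.epoch[0]:
            raise ConfigurationError("coupling_lag must be shorter than the epoch")


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple,
    fs: float,
    exponent: float = 1.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Power-law (1/f^exponent power) noise by spectral shaping of white noise.

    The last axis is time. The DC bin is zeroed; the output is rescaled to the
    requested RMS amplitude.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return amplitude * shaped / rms


def _epoch_times(epoch: tuple, fs: float) -> tuple[np.ndarray, int]:
    t_start, t_end = epoch
    n = int(round((t_end - t_start) * fs))
    t0_index = int(round(-t_start * fs))
    times = (np.arange(n) - t0_index) / fs
    return times, t0_index


def make_phase_coded_trials(cfg: SynthTrialConfig) -> tuple[TrialSet, LabelSet]:
    """Generate balanced two-condition trials with planted phase opposition.

    Each trial is 1/f noise plus a continuous sinusoid at ``f0`` whose phase
    is pinned at ``t_lock`` (back-propagated across the epoch at constant
    frequency): ``x(t) = A cos(2 pi f0 (t - t_lock) + phi_i)``, so the
    instantaneous phase of the oscillation at ``t_lock`` equals ``phi_i``.
    """
    rng = np.random.default_rng(cfg.seed)
    times, t0_index = _epoch_times(cfg.epoch, cfg.fs)
    n_per = cfg.n_trials_per_condition
    n_trials = 2 * n_per

    labels = np.concatenate([np.ones(n_per, int), np.zeros(n_per, int)])
    centres = np.where(labels == 1, cfg.mu_high, cfg.mu_high + np.pi)
    if cfg.kappa > 0:
        phis = rng.vonmises(centres, cfg.kappa)
    else:
        phis = rng.uniform(-np.pi, np.pi, size=n_trials)

    osc = cfg.osc_amplitude * np.cos(
        2 * np.pi * cfg.f0 * (times[None, :] - cfg.t_lock) + phis[:, None]
    )
    noise = one_over_f_noise(
        rng,
        (n_trials, cfg.n_channels, times.size),
        cfg.fs,
        cfg.noise_exponent,
        cfg.noise_amplitude,
    )
    data = noise + osc[:, None, :]

    meta = {
        "generator": "make_phase_coded_trials",
        "config": asdict(cfg),
        "planted_phases": phis.tolist(),
        "seed": cfg.seed,
    }
    trials = TrialSet(data=data, fs=cfg.fs, t0_index=t0_index, meta=meta)
    return trials, LabelSet(labels=labels)


def make_agency_labels_from_phase(
    phases: np.ndarray,
    p0: float,
    beta: float,
    phi_opt: float,
    seed: int = 0,
) -> LabelSet:
    """Draw binary outcomes with a cosine link on phase.

    ``P(label_i = 1) = p0 + beta * cos(phase_i - phi_opt)``.
    """
    if not (0 <= p0 - abs(beta) and p0 + abs(beta) <= 1):
        raise ConfigurationError("p0 +/- beta must stay within [0, 1]")
    rng = np.random.default_rng(seed)
    phases = np.asarray(phases, dtype=float)
    p = p0 + beta * np.cos(phases - phi_opt)
    labels = (rng.uniform(size=phases.shape) < p).astype(int)
    return LabelSet(labels=labels)


def make_spike_trains(
    trials: TrialSet, cfg: SpikeSynthConfig, f0: float
) -> SpikeTrainSet:
    """Generate phase-modulated Poisson spikes locked to the planted oscillation.

    Rate: ``lambda(t) = base_rate * (1 + m cos(phi_f0(t) - preferred_phase))``
    with ``phi_f0(t)`` the planted-oscillation instantaneous phase, taken from
    the trial metadata written by :func:`make_phase_coded_trials`. Spikes are
    drawn by Poisson thinning, giving exact continuous event times.
    """
    meta = trials.meta
    if "planted_phases" not in meta:
        raise ConfigurationError("trials carry no planted oscillation truth")
    phis = np.asarray(meta["planted_phases"], dtype=float)
    t_lock = meta["config"]["t_lock"]
    t_start = trials.times[0]
    t_end = trials.times[-1]
    duration = t_end - t_start
    if cfg.base_rate * duration < 1:
        raise ConfigurationError("expected spike count below one per trial")

    rng = np.random.default_rng(cfg.seed)
    lam_max = cfg.base_rate * (1 + cfg.mod_depth)
    rows = []
    for unit in range(cfg.n_units):
        for trial in range(trials.n_trials):
            n_cand = rng.poisson(lam_max * duration)
            t_cand = np.sort(rng.uniform(t_start, t_end, size=n_cand))
            phase = 2 * np.pi * f0 * (t_cand - t_lock) + phis[trial]
            lam = cfg.base_rate * (
                1 + cfg.mod_depth * np.cos(phase - cfg.preferred_phase)
            )
            keep = rng.uniform(0, lam_max, size=n_cand) < lam
            for t in t_cand[keep]:
                rows.append((unit, trial, t))
    events = pd.DataFrame(rows, columns=["unit", "trial", "time_s"])
    return SpikeTrainSet(
        events=events,
        meta={"config": asdict(cfg), "f0": f0, "seed": cfg.seed},
    )


def _narrowband(rng, n_trials, n_samples, fs, band, amplitude):
    """Narrowband stochastic oscillations by spectral masking of white noise.

    Returns the complex analytic signals, RMS-normalised to ``amplitude``.
    A stochastic (wandering-phase) carrier is essential: with pure sinusoids
    the seed-target phase difference is constant at every imposed lag and
    lagged coherence carries no directional information.
    """
    white = rng.standard_normal((n_trials, n_samples))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    fc = 0.5 * (band[0] + band[1])
    bw = max(0.5 * (band[1] - band[0]), 1e-6)
    mask = np.exp(-0.5 * ((freqs - fc) / (bw / 2.0)) ** 2)
    mask[0] = 0.0
    shaped = np.fft.irfft(spectrum * mask, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    shaped = amplitude * shaped / rms
    return scipy.signal.hilbert(shaped, axis=-1)


def make_coupled_source_pair(
    cfg: CoupledPairConfig, n_trials: int
) -> tuple[TrialSet, np.ndarray]:
    """Generate a seed/target channel pair with phase-gated lagged coupling.

    The seed's oscillatory phase at ``t_lock`` (theta_i, uniform across
    trials) is drawn first and recorded. On gated trials (theta_i within pi/3
    of ``gate_phase``) the seed drives: the target is noise plus a copy of
    the seed oscillation delayed by ``coupling_lag``. On the remaining trials
    the direction is reversed (the target drives and the seed receives the
    lagged copy), with the driver's phase rotated so the seed still shows
    theta_i at ``t_lock``. The oscillations are narrowband stochastic
    signals in ``band``, not pure sinusoids, so lagged phase coherence is
    informative about the coupling delay.

    Returns the two-channel TrialSet (channel 0 = seed, 1 = target) and the
    per-trial seed phases at ``t_lock``.
    """
    rng = np.random.default_rng(cfg.seed)
    times, t0_index = _epoch_times(cfg.epoch, cfg.fs)
    n = times.size
    lag_samp = int(round(cfg.coupling_lag * cfg.fs))
    pad = lag_samp
    idx_lock = t0_index + int(round(cfg.t_lock * cfg.fs))

    thetas = rng.uniform(-np.pi, np.pi, size=n_trials)
    d = np.angle(np.exp(1j * (thetas - cfg.gate_phase)))
    gated = np.abs(d) < np.pi / 3

    # drivers live on a padded axis (pad extra samples before epoch start)
    drivers = _narrowband(rng, n_trials, n + pad, cfg.fs, cfg.band,
                          cfg.osc_amplitude)
    seed_sig = np.empty((n_trials, n))
    targ_sig = np.empty((n_trials, n))
    for i in range(n_trials):
        a = drivers[i]
        if gated[i]:
            # rotate the driver so the seed phase at t_lock equals theta_i
            rot = np.exp(1j * (thetas[i] - np.angle(a[pad + idx_lock])))
            a = a * rot
            seed_sig[i] = np.real(a[pad:])
            targ_sig[i] = cfg.coupling_gain * np.real(
                a[pad - lag_samp : pad - lag_samp + n]
            )
        else:
            # target drives; the lagged copy arriving at the seed must carry
            # phase theta_i at t_lock
            rot = np.exp(1j * (thetas[i] - np.angle(a[pad + idx_lock - lag_samp])))
            a = a * rot
            targ_sig[i] = np.real(a[pad:])
            seed_sig[i] = cfg.coupling_gain * np.real(
                a[pad - lag_samp : pad - lag_samp + n]
            )

    noise = one_over_f_noise(
        rng, (n_trials, 2, times.size), cfg.fs, cfg.noise_exponent,
        cfg.noise_amplitude,
    )
    data = noise
    data[:, 0, :] += seed_sig
    data[:, 1, :] += targ_sig

    meta = {
        "generator": "make_coupled_source_pair",
        "config": asdict(cfg),
        "seed_phases": thetas.tolist(),
        "gated": gated.tolist(),
        "seed": cfg.seed,
    }
    trials = TrialSet(
        data=data, fs=cfg.fs, t0_index=t0_index,
        channel_ids=["seed", "target"], meta=meta,
    )
    return trials, thetas


def make_subject_cohort(
    n_subjects: int,
    alpha_peak_range: tuple = (8.0, 13.0),
    template: SynthTrialConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Generate a cohort of subjects with individually planted alpha peaks.

    Each subject's trials carry a planted oscillation at that subject's alpha
    frequency (drawn uniformly in ``alpha_peak_range``) on a 1/f background,
    so both the spectral alpha bump and the phase-opposition frequency sit at
    the same planted f0.

    Returns a list of dicts with keys ``trials``, ``labels``, ``f0``, ``cfg``.
    """
    if template is None:
        template = SynthTrialConfig()
    rng = np.random.default_rng(seed)
    lo, hi = alpha_peak_range
    cohort = []
    for s in range(n_subjects):
        f0 = float(rng.uniform(lo, hi))
        cfg = SynthTrialConfig(
            **{
                **asdict(template),
                "f0": f0,
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        trials, labels = make_phase_coded_trials(cfg)
        cohort.append({"trials": trials, "labels": labels, "f0": f0, "cfg": cfg})
    return cohort
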