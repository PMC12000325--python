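"""Core in-memory containers shared across the analysis chain.

All time axes are in seconds relative to movement onset (t = 0); pre-movement
times are negative. Epoch windows are closed-open ``[a, b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TrialSet",
    "LabelSet",
    "AnalyticMap",
    "SpikeTrainSet",
    "POPMap",
    "PhasePartition",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TrialSet:
    """Trial-epoched multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Real-valued voltage traces (µV, arbitrary units for synthetic data).
    fs : float
        Sampling rate in Hz.
    t0_index : int
        Sample index of movement onset (t = 0).
    channel_ids, trial_ids : sequences, optional
        Identifiers; defaulted to integer ranges.
    meta : dict
        Free-form provenance (generator config, planted ground truth, seeds).
        Unknown keys are preserved verbatim through container round-trips.
    """

    data: np.ndarray
    fs: float
    t0_index: int
    channel_ids: list = None
    trial_ids: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be (n_trials, n_channels, n_samples)")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not (0 <= self.t0_index < self.data.shape[2]):
            raise ConfigurationError("t0_index outside epoch")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.data.shape[1]))
        if self.trial_ids is None:
            self.trial_ids = list(range(self.data.shape[0]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to movement onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs

    def time_to_index(self, t: float) -> int:
        """Nearest sample index for a time in seconds (ties toward earlier)."""
        return int(np.ceil(t * self.fs + self.t0_index - 0.5))


@dataclass
class LabelSet:
    """Per-trial behavioural labels.

    ``labels`` holds 1 for condition A ("high"), 0 for condition B ("low") and
    -1 for excluded trials. Raw 1-9 agency ratings and go-cue-to-movement
    delays are optional companions used by the rating workflows.
    """

    labels: np.ndarray
    ratings: np.ndarray | None = None
    delays: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        for name in ("ratings", "delays"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.labels.shape:
                    raise ConfigurationError(f"{name} length mismatch")
                setattr(self, name, v)

    @property
    def n_trials(self) -> int:
        return self.labels.size

    @property
    def high_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def low_mask(self) -> np.ndarray:
        return self.labels == 0


@dataclass
class AnalyticMap:
    """Complex analytic signal per (trial, channel, frequency, sample).

    Magnitude is instantaneous amplitude; the argument is instantaneous phase.
    ``valid`` flags samples free of edge contamination (wavelet support or
    causal-filter startup transient); invalid samples are never silently
    zero-filled.
    """

    values: np.ndarray  # complex, (n_trials, n_channels, n_freqs, n_samples)
    freqs: np.ndarray
    times: np.ndarray
    method: str  # "morlet" | "causal_hilbert"
    valid: np.ndarray = None  # bool, (n_freqs, n_samples)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.ones((self.freqs.size, self.times.size), dtype=bool)

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-6:
            raise ValueError(f"frequency {f} Hz not on the analytic grid")
        return i

    def time_index(self, t: float) -> int:
        return int(np.ceil((t - self.times[0]) * self._fs() - 0.5))

    def _fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def phases(self, channel: int = 0) -> np.ndarray:
        """Instantaneous phase, (n_trials, n_freqs, n_samples)."""
        return np.angle(self.values[:, channel])


@dataclass
class SpikeTrainSet:
    """Spike events relative to movement onset.

    Backed by a DataFrame with columns ``unit``, ``trial``, ``time_s``.
    """

    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"unit", "trial", "time_s"}
        if not required.issubset(self.events.columns):
            raise ConfigurationError(f"spike table needs columns {sorted(required)}")

    @property
    def n_spikes(self) -> int:
        return len(self.events)

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.events["unit"].to_numpy())


@dataclass
class POPMap:
    """Phase opposition product per (frequency, time) with its constituents."""

    pop: np.ndarray  # (n_freqs, n_times)
    itc_all: np.ndarray
    itc_a: np.ndarray
    itc_b: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n: int
    n_a: int
    n_b: int


@dataclass
class PhasePartition:
    """Trials split around an individual optimal phase angle."""

    optimal_angle: float
    optimal: np.ndarray  # trial indices within half_width of the optimal angle
    non_optimal: np.ndarray  # within half_width of the antiphase
    half_width: float
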