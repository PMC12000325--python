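"""Individual alpha-peak estimation and its alignment with phase opposition.

The broadband background of cortical power spectra follows an approximate
power law ``P(f) = a * f**(-b)``. Fitting that law on 5-30 Hz in log-log
coordinates and subtracting it isolates narrowband structure; the individual
alpha peak is the point of maximum convexity (most negative discrete second
difference, i.e. the sharpest local peak) of the residual within 8-13 Hz.
The per-subject frequency of strongest phase opposition is expected to track
this peak when the opposition rides on the subject's alpha rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .containers import ConfigurationError
from .permutation import PermutationResult

__all__ = [
    "SpectrumFit",
    "fit_background_one_over_f",
    "individual_alpha_peak",
    "peak_pop_frequency",
    "peak_alignment_regression",
]


@dataclass
class SpectrumFit:
    freqs: np.ndarray  # fit-range frequency grid
    raw_power: np.ndarray  # raw power on the fit range
    amplitude: float  # power-law a
    exponent: float  # power-law b (power ~ a * f**-b)
    residual: np.ndarray  # raw minus back-transformed fit


def fit_background_one_over_f(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_range: tuple = (5.0, 30.0),
) -> SpectrumFit:
    """Fit the 1/f background as a straight line in log-log coordinates.

    The residual (raw minus back-transformed power law) isolates narrowband
    bumps riding on the background.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    if sel.sum() < 10:
        raise ConfigurationError("need >= 10 frequency bins in the fit range")
    f, p = freqs[sel], power[sel]
    if np.any(p <= 0):
        raise ConfigurationError("non-positive power in the fit range")
    slope, intercept = np.polyfit(np.log(f), np.log(p), 1)
    background = np.exp(intercept) * f**slope
    return SpectrumFit(
        freqs=f,
        raw_power=p,
        amplitude=float(np.exp(intercept)),
        exponent=float(-slope),
        residual=p - background,
    )


def individual_alpha_peak(
    fit: SpectrumFit,
    band: tuple = (8.0, 13.0),
    smooth_bins: int = 3,
    min_relative_residual: float = 0.05,
) -> float | None:
    """Alpha peak as the point of maximum convexity of the 1/f residual.

    The residual is smoothed with a short moving average, and among interior
    local maxima within ``band`` the frequency with the most negative second
    difference is returned. ``None`` when the open band interior holds no
    local maximum exceeding ``min_relative_residual`` of the fitted
    background (guards against fit ripple being read as a peak). Band-edge
    peaks are rejected: edge curvature is unreliable.
    """
    f = fit.freqs
    if band[0] < f[0] or band[1] > f[-1]:
        raise ConfigurationError("band outside the fitted range")
    r = fit.residual
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        r = np.convolve(r, kernel, mode="same")
    background = fit.raw_power - fit.residual
    d2 = np.full_like(r, np.nan)
    d2[1:-1] = r[2:] - 2 * r[1:-1] + r[:-2]
    interior = np.zeros(f.size, dtype=bool)
    interior[1:-1] = (f[1:-1] > band[0]) & (f[1:-1] < band[1])
    local_max = np.zeros(f.size, dtype=bool)
    local_max[1:-1] = (
        (r[1:-1] >= r[:-2])
        & (r[1:-1] >= r[2:])
        & (r[1:-1] > min_relative_residual * background[1:-1])
    )
    cand = interior & local_max
    if not cand.any():
        return None
    idx = np.flatnonzero(cand)
    best = idx[np.argmin(d2[idx])]
    return float(f[best])


def peak_pop_frequency(
    perm_result: PermutationResult,
    window: tuple = (-0.5, 0.0),
) -> dict:
    """Frequency of strongest phase opposition in a time window.

    POP values (observed and permuted) are averaged over the window per
    frequency; the returned frequency minimises the permutation p of the
    window-averaged POP. Several frequencies can tie at the attainable
    minimum p when the permutation count is finite; ties are resolved by the
    strongest observed window-averaged POP, then by the lowest frequency.
    When even the best frequency is non-significant (p > 0.05) the pick is
    flagged: on null data it is seed-dependent noise.
    """
    times = perm_result.times
    tmask = (times >= window[0]) & (times < window[1])
    if not tmask.any():
        raise ConfigurationError("empty window")
    obs = perm_result.observed[:, tmask].mean(axis=1)  # per frequency
    nulls = perm_result.nulls[:, :, tmask].mean(axis=2)  # (n_perm, n_freqs)
    n_perm = perm_result.n_perm
    p = (1 + np.sum(nulls >= obs[None], axis=0)) / (1 + n_perm)
    tied = np.flatnonzero(p == p.min())
    best = int(tied[np.argmax(obs[tied])])
    return {
        "frequency": float(perm_result.freqs[best]),
        "p": float(p[best]),
        "significant": bool(p[best] <= 0.05),
        "p_per_frequency": p,
    }


def peak_alignment_regression(
    alpha_peaks: np.ndarray, pop_peaks: np.ndarray
) -> dict:
    """Least-squares line and Pearson correlation between the two frequency
    estimates across subjects (pairs with undefined peaks dropped)."""
    a = np.asarray(alpha_peaks, dtype=float)
    b = np.asarray(pop_peaks, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ConfigurationError("need >= 3 subjects with defined peaks")
    res = scipy.stats.linregress(a, b)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "correlation": float(res.rvalue),
        "p": float(res.pvalue),
        "n_subjects": int(a.size),
    }
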