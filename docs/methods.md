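# Methods

This note documents the statistical model behind `phaseopp`, the conventions
and defaults that matter, and the design choices made where more than one
reasonable implementation exists. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Trial-epoched data are real-valued arrays of shape (trials × channels ×
samples) at a fixed sampling rate, time-locked to movement onset: the time
axis is in seconds with t = 0 at onset, pre-movement times negative, and all
analysis windows closed-open `[a, b)`. Behavioural labels are per-trial:
binary (condition A = "high", B = "low"), or raw 1–9 ratings with
go-cue-to-movement delays, in which case ratings are first detrended (ordinary
least squares of rating on delay, within participant) and the highest and
lowest thirds of the residuals define the two conditions, discarding the
uninformative middle.

Spike-to-sample mapping uses the nearest sample with ties broken toward the
earlier sample — deterministic and unbiased at physiological rates.

## Analytic signals

**Morlet route (main).** Complex Morlet convolution over 10 linearly spaced
frequencies from 4 to 13 Hz, with the wavelet width parameter (number of
cycles) set to 2π ≈ 6.283 for intracranial-quality signals and 4π for
lower-SNR scalp EEG. Instantaneous power is the squared magnitude of the
complex coefficient, phase its argument. The implementation is backed by
`mne.time_frequency.tfr_array_morlet`. Samples closer to either epoch edge
than **three standard deviations of the wavelet's Gaussian envelope**
(σ_t = n_cycles / 2πf) carry an explicit invalid flag; they are never
silently zero-filled. Three sigma (rather than the full 5σ numerical support)
bounds the edge contamination by the e^{−4.5} ≈ 1% envelope tail while
keeping usable pre-movement windows inside epochs of a few seconds. The
Morlet amplitude normalisation follows mne's convention; phase, and
therefore every statistic in the package, is unaffected by that choice.

**Causal route (control).** A linear-phase FIR band-pass (Hamming design,
default ≈ 3 cycles of the low band edge, DC gain forced to exactly zero) is
converted to its analytic counterpart by discarding negative frequencies and
applied in a single forward pass. The output at time t therefore depends
only on input samples ≤ t, with a fixed, reported group delay of
(n_taps − 1)/2fs; the first n_taps samples are flagged as startup transient.
Re-running the phase-opposition analysis through this route verifies that a
pre-movement effect is not an artefact of the non-causal wavelet's symmetric
support. The two routes agree within ~0.3 rad at band centre on stationary
oscillations (tested).

## Phase opposition and its inference

With normalised analytic vectors ω_i/|ω_i|, ITC over a trial set is the
resultant length of the unit phase vectors and

POP = ITC_A · ITC_B − ITC²_ALL, per (frequency, time).

POP ∈ [−1, 1], is invariant to global phase rotation, symmetric in the two
labels, and equals 1 for equal-sized, perfectly opposed conditions. Amplitude
never enters (zero-amplitude samples are undefined-phase and must be masked).

Inference: condition labels are shuffled preserving group sizes; the
one-sided p-value is add-one smoothed, p = (1 + #{perm ≥ obs})/(1 + n_perm),
which avoids zero p-values and makes the minimum attainable p equal to
1/(n_perm + 1). For family-wise control, each permutation's map is converted
to p-values against the full permutation set, p is mapped to T by the
one-sided standard-normal quantile, supra-threshold (T ≥ 2, p ≈ 0.05)
4-connected components are scored by their T-sum, and a cluster's corrected
p counts permutations whose maximal cluster score reaches it. The point-level
threshold is one-sided, matching the one-sided POP comparison. The default
correction window is the last 0.5 s before movement onset. Defaults:
10 000 permutations for full analyses, 500–1000 in the test profile.

The group-level test averages window-mean POP across subjects, with labels
shuffled within subject only, and counts larger permuted group means.

**Peak POP frequency.** The per-subject "frequency of strongest opposition"
minimises the permutation p of window-averaged POP. At finite permutation
counts several frequencies often tie at the attainable minimum p; ties are
resolved by the strongest observed window-mean POP and only then by the
lowest frequency. (Tie-breaking purely by lowest frequency would
deterministically return the bottom of the grid for any strong broadband
effect.) A non-significant best frequency is flagged: on null data the pick
is seed-dependent noise.

## Optimal phases and partitions

The optimal phase angle is the unit-vector average of the high-condition
circular mean and the antiphase of the low-condition circular mean —
unweighted, since there is no principled weighting between the two direction
estimates. Circular means are computed by resultant vectors and declared
undefined below a resultant length of 10⁻¹². Trials strictly within π/3 of
the optimal angle are "optimal", strictly within π/3 of its antiphase
"non-optimal"; boundary trials are excluded (a measure-zero choice made for
determinism). Under uniform phases each group captures ≈ 1/3 of trials.
Phase-binned outcome probabilities use equal-width bins of circular distance
to a reference angle with normal-approximation binomial confidence intervals
(66% by default, matching the error-bar convention used for such plots).

## Spike–field coupling

PLV(f) is the resultant length of oscillation phases sampled at spike times,
pooled over units (per-unit preferred angles are a separate operation; units
below 10 spikes are flagged unreliable). The 5-bin spike-phase histogram is
aligned so that bin 0 is centred on the global preferred phase; under no
coupling each bin holds 1/5 of the spikes. The synthetic spike generator is
an inhomogeneous Poisson process, rate λ(t) = r₀(1 + m cos(φ(t) − φ_pref)),
sampled exactly by thinning; its stationary spike-phase density is
(1 + m cos)/2π, so bin probabilities and the PLV (Bessel ratio I₁/I₀ for von
Mises phases) have closed-form oracles.

## Connectivity and directionality

**Debiased WPLI.** With imaginary cross-spectrum observations y_j pooled over
trials and window samples (default window 0.2–1.2 s post-movement; grid of
42 linearly spaced frequencies, 4–45 Hz),

dWPLI = ((Σy)² − Σy²) / ((Σ|y|)² − Σy²).

The estimator discounts zero-lag (volume-conduction-like) mixing and removes
the small-sample bias of the squared WPLI; it is invariant to amplitude
rescaling of either signal. The degenerate case — imaginary parts all zero
up to rounding, as for an exact zero-lag copy — is reported as 0 with a flag
rather than NaN, since zero-lag mixing is precisely what WPLI is built to
discount. Degeneracy is declared relative to the cross-spectrum magnitude
(den ≤ 10⁻²⁰ × (Σ|x·ȳ|)²) because floating-point dust keeps the raw
denominator from being exactly zero. It is implemented here directly from
the estimator's definition.

**Lag-ITC directionality.** For an imposed delay L on the target (positive =
target delayed), the phase difference φ_seed(t) − φ_target(t + L) is formed
per trial and window sample at each of 9, 10, 11 and 12 Hz; the ITC is taken
across trials per (frequency, sample) and then averaged over samples and
frequencies, leaving a coherence curve over lags. Averaging after the
trialwise ITC keeps the statistic an inter-trial coherence proper; the
alternative orderings differ negligibly for narrowband signals. A peak at
positive lag means the seed's present predicts the target's future (seed
leads). The default lag grid is ±100 ms in 5 ms steps (constructed as exact
integer multiples so that lag 0 is exact); peak ties are broken toward zero
lag; a flat curve yields no peak and excludes the subject from the paired
comparison with a warning. The peak-lag contrast between optimal and
non-optimal phase partitions uses a paired t statistic implemented from its
definition. Group frequency-cluster correction uses subject sign-flip
permutations on |t| ≥ 2 over the frequency axis; macro-region aggregation is
an unweighted mean over member targets with Bonferroni correction across
groups.

## Alpha peaks

The 1/f background is a least-squares line in log-power versus log-frequency
over 5–30 Hz; the residual is the raw spectrum minus the back-transformed
power law. The individual alpha peak is the point of **maximum convexity**
of the residual in 8–13 Hz: after a 3-bin moving-average smoothing, the
interior local maximum with the most negative discrete second difference.
Local maxima must exceed 5% of the fitted background (guarding against fit
ripple being read as a peak), and band-edge bins are never returned —
curvature at the edge is one-sided and unreliable. Both the smoothing window
and the prominence floor are this package's choices where the procedure is
otherwise underdetermined. The estimator is equivariant under rescaling the
whole spectrum.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seeded `numpy.random.Generator` per call,
record the seed and planted truth in output metadata, and are
bit-reproducible.

- **Phase-coded trials**: 1/f background (spectral shaping of white noise,
  exponent 1.0 — the canonical broadband LFP/EEG slope) plus a continuous
  sinusoid whose phase is pinned at the planted (f₀, t_lock) point and
  back-propagated at constant frequency. Condition B's phase centre is
  hard-coded to μ_high + π (pure opposition, the construct under test);
  κ = 0 plants nothing. Defaults: 100 trials/condition, fs = 250 Hz, epoch
  −2 to +1 s, f₀ = 8 Hz, t_lock = −256 ms, κ = 5 — the regime of a clear
  single-subject effect. Because the planted oscillation is sustained, the
  opposition is detectable across the whole epoch at f₀, not only at t_lock;
  tests that probe localisation therefore construct blocks directly in phase
  space.
- **Cosine-link outcomes**: P(high) = p₀ + β·cos(φ − φ_opt). No quantitative
  effect size exists to copy for the phase→behaviour link, so p₀ and β are
  free simulation knobs (defaults 0.5/0.3 in tests).
- **Coupled source pairs**: narrowband *stochastic* oscillations (Gaussian
  spectral mask in the band) — essential, since with pure sinusoids the
  seed–target phase difference is constant at every lag and lagged coherence
  carries no directional information. The coupling direction is gated by the
  seed phase at t_lock; the receiver gets the driver delayed by the coupling
  lag (30 ms, gain 0.9 by default) plus independent 1/f noise.
- **Subject cohorts**: per-subject planted alpha frequency drawn uniformly
  in the requested range; the same oscillation provides both the spectral
  bump and the phase-opposition frequency. Cohort benchmarks draw peaks
  from 8.3–12.7 Hz so that planted peaks remain strictly interior to the
  8–13 Hz estimation band (the estimator rejects edge bins by design).

Not emulated: volume conduction and leadfields, realistic electrode
montages, artefacts, non-stationary background, multiple simultaneous
oscillators. Passing the planted-recovery benchmarks therefore demonstrates
the correctness and calibration of the estimators under their assumed signal
model, not robustness to every property of real recordings.

## Problem sizes and numerical choices

The test and acceptance profiles run at fs = 250 Hz (200 Hz for coupled
pairs), 20–100 trials per condition, 300–1000 permutations, 100–200 null
replications and 10–20 recovery runs — sizes at which every Monte Carlo
tolerance in the suite is comfortably inside its sampling noise.
Determinism: identical seeds give bit-identical outputs end to end; CSV
output uses nine significant digits so repeated runs are byte-identical.
Degenerate inputs are handled explicitly throughout: zero-amplitude phases
raise unless masked, zero-variance t-statistics are flagged as 0, empty
histogram bins are flagged rather than interpolated, and an empty
supra-threshold set is an empty cluster result, not an error.

## Known limitations

- The POP permutation scheme assumes exchangeability of trials under the
  null within a subject; slow nonstationarities violating this are not
  modelled.
- The causal analytic route has a frequency-dependent amplitude response
  near the band edges; only its phase is used by the package's statistics.
- Cluster inference controls the family-wise error of the *maximal* cluster
  statistic; corrected p-values for secondary clusters are conservative.
- The alpha-peak estimator models a single bump on a pure power law; knees
  or multiple overlapping peaks are out of scope.
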