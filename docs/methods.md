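# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate. It complements the README's
overview; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral pipeline

Epochs are non-overlapping 1 s windows; a 3-min baseline at 1 kHz yields 180
of them, and trailing partial samples are discarded. Artifact rejection is a
deterministic surrogate for visual screening: an epoch is excluded iff its
absolute amplitude exceeds a threshold (default 100 μV) on any channel.
Blinks and muscle bursts are large-amplitude events, so the threshold
reproduces the screening decision reproducibly; the threshold is a parameter,
not a constant.

Power is the squared modulus of the one-sided DFT of the Hann-windowed epoch
at integer-Hz bins 0–40. No window amplitude correction is applied: every
epoch uses the same window, and the baseline normalization cancels any common
factor. The log transform is the natural log with a floor of 1e-12 μV²
(noise-free synthetic epochs produce exactly zero bins). Averaging over
retained epochs and over electrodes are both plain arithmetic means, so
their order is immaterial (tested). Alpha and beta band power are means over
bins {9,10,11} and {19,20,21} — the stimulation frequencies ± 1 Hz.

The normalized change NP = (A − R)/R is applied to log band power, with a
guard rejecting |R| ≤ 1e-6: a log-power baseline that close to zero makes
the ratio meaningless, and the guard is where the choice of log base would
otherwise hide.

## MEP pipeline

Tukey fences use linear-interpolation quartiles (numpy's default, R type 7);
the convention is isolated in `tukey_fences` so a different hinge rule can be
swapped in. Removed interior trials are linearly interpolated between the
nearest retained neighbours; gaps before the first (after the last) retained
trial take that trial's value, since interpolation is undefined beyond the
ends.

The local linear trend model is estimated by maximum marginal likelihood:
the Kalman filter's prediction-error decomposition, optimized over
log-variances by Nelder–Mead from three starting points derived from the
variance of the first differences (multi-start avoids boundary local optima
where one disturbance variance collapses to zero). The initial level and
slope are diffuse — prior N(0, κ) with κ = 1e7 — and the first two
prediction-error terms (one per diffuse state) are excluded from the
likelihood. Smoothed states come from fixed-interval (RTS) smoothing; the
predicted covariance is inverted by pseudoinverse because it degenerates when
estimated variances hit zero (e.g. an exactly linear series). Variance
estimates are constrained nonnegative by the log parameterization, with the
optimizer clipped at e^±40.

The "Bayesian" alternative is a random-walk Metropolis sampler over
log-variances with half-normal priors on the disturbance SDs (scale = the
sample SD of the series); states are smoothed at the posterior-median
variances. The MLE path is the default because it is deterministic and
directly testable against a dense joint-Gaussian posterior oracle (agreement
to ~1e-10 for n ≤ 30 with matched κ).

Post-stimulation NP uses the smoothed level, not the raw amplitudes —
the point of the state-space model is that the level, not the noisy
observation, carries the excitability signal. NP is computed per trial and
aggregated downstream (per-series means feed the condition comparison). The
baseline R is the mean of the outlier-cleaned pre-stimulation amplitudes.
Pre and post blocks are cleaned and interpolated independently.

## Statistical decision chain

The normality gate is the Kolmogorov–Smirnov test with the Lilliefors
correction (statsmodels' precomputed null table), because the null's mean
and SD are estimated from the sample; the uncorrected test is exposed as
`naive_ks` for comparison. The gate is applied per condition; if any
condition rejects at α, the nonparametric branch runs. A consequence worth
knowing: on exactly Gaussian data with three conditions the parametric branch
is chosen with probability ≈ (1 − α)³ ≈ 0.86, not 1 − α.

Friedman's test uses within-block mid-ranks and the tie-corrected statistic;
df = k − 1. For b ≤ 8 blocks the exact permutation p is enumerated by
dynamic programming over column-sum states (the statistic depends on the
permuted table only through its column sums, collapsing (k!)^b to a few
thousand states). The chi-squared approximation tracks the exact tail well
where it matters (differences < 0.05 for exact p ≤ 0.2 at b ≤ 6) but can
differ by > 0.1 in the mid-p range, where the exact null has few atoms.

Steel–Dwass: for each pair of conditions the pooled data are mid-ranked, the
rank sum W standardized with the tie-corrected variance
Var[W] = n₁n₂/(N(N−1)) Σ(r − r̄)², and the familywise-adjusted p obtained by
referring q = z·√2 to the Studentized-range distribution (k groups, infinite
df). The adjusted p applies a 0.5 continuity correction to |W − E[W]| before
standardizing: the rank sum is discrete, and the corrected tail follows the
exact max-|z| permutation distribution to a few thousandths at n = 4/group,
whereas the uncorrected tail is off by ~0.02–0.03 there. The reported
statistic (`z_pair`) is uncorrected. For total N ≤ 12 the exact familywise p
is enumerated over all reassignments of the pooled values (max-|z|
distribution), with caching over repeated subset pairs.

The parametric branch is statsmodels' repeated-measures ANOVA (condition ×
time when a second factor is present, one-way within-subject otherwise),
with paired-t Bonferroni contrasts. Identical-valued designs (F = 0/0) are
reported as the null outcome F = 0, p = 1.

## Montage evaluation

ROI averaging is a weighted arithmetic mean of per-element normal-component
field values (weights = element areas/volumes). Group dispersion uses the
sample (n−1) SD. The selection rule makes the informal "high and stable"
criterion explicit: among montages whose group mean reaches ≥ 90% of the
best mean (threshold configurable), select the minimal-RSD one, ties broken
by label. The full ranked table is always emitted so the rule is auditable.
Internal units are mV/m; V/m input is converted on request.

A limit of the stability criterion worth stating: with 18 subjects, the
sampling SE of a between-montage difference in sample RSD is ≈ 7 percentage
points, so two montages whose population RSDs differ by only ~2 points (as
the two best candidates here do) cannot be separated reliably — the
selection rate for the true winner plateaus around 0.8 under these
conditions regardless of the combination rule. Dose helpers:
a 1.8 cm square electrode has 3.24 cm²; a 0.6 mA peak-to-peak waveform has
a 0.3 mA single-phase amplitude, hence 0.093 mA/cm² under one electrode.

## Synthetic data

The EEG generator produces a 1/f^α Gaussian background (white noise shaped
in the frequency domain, α default 1, gain held constant below 1 Hz, DC
removed, unit RMS rescaled to 10 μV), sinusoidal band components at 10 and
20 Hz (defaults 5 and 3 μV), and blink transients (400 ms half-sines at
Poisson times, 150 μV on anterior channels, attenuated toward posterior
sites). Channels mix a shared source with independent noise (default weight
0.5), a stand-in for volume conduction. The generator does not emulate
narrow-band amplitude modulation, non-stationarity, line noise, or real
artifact morphology — passing tests show the pipeline recovers injected
band-power changes against a realistic noise floor, not that it handles
every real-world contaminant.

The MEP generator simulates the local linear trend model exactly (level and
slope random walks plus observation noise; defaults: level 500 μV, σ_obs
50 μV, σ_level 5 μV, σ_slope 0.5 μV/trial, 20 trials), with optional
multiplicative outliers (probability 0.05, factor 3) that leave the latent
states untouched; the true states are returned for recovery tests. Real MEP
noise is heavier-tailed and amplitude-dependent; the generative match to the
fitted model is deliberate, since parameter/state recovery is the property
under test.

The field-table generator draws per-subject ROI means from gamma margins
moment-matched to each montage's target mean and SD. Gamma rather than a
truncated Gaussian because the most variable montages have RSD > 100%, which
no Gaussian truncated at zero can represent (its RSD is bounded below 100%),
while gamma matches any positive (mean, SD) exactly and is strictly
nonnegative. Montages are coupled within subject by a Gaussian copula
(correlation 0.85): the same head anatomy — skull thickness, CSF layer —
scales every montage's field in a given subject, and ignoring that coupling
would overstate the independence of the per-montage group statistics.

The end-to-end study simulator mirrors the experimental design — 16
participants, three sessions (alpha-, beta-, sham-tACS), 3-min pre/post EEG
and 20-trial pre/post MEP blocks (unconditioned and conditioned at half
amplitude) — with injected effects in the studied directions: the post 10 Hz
(20 Hz) amplitude doubled after alpha- (beta-) tACS and the post MEP level at
0.7× baseline for both active conditions. Between-subject lognormal spread
(CV 0.2 on oscillation amplitudes, 0.15 on MEP level) keeps units
heterogeneous.

## Problem sizes and runtimes

Chosen so the full suite and the acceptance script each run in minutes on
one core: smoother–oracle agreement at n ∈ {5,10,20,30}; variance recovery
over 100 series of n = 200 (truth σ² = 25/1/0.01); Friedman type-I error
over 2000 null tables of 16 × 3; Steel–Dwass familywise error over 2000
null draws at n = 16/group and exact enumeration at 3 × 4; ERS recovery
over 20 pre/post pairs of 180 s recordings; montage selection over 200
tables of 18 × 7; end-to-end pattern over 12 full studies.

## Known limitations

* The artifact-rejection surrogate is amplitude-only; no EOG regression or
  ICA.
* The exact Steel–Dwass enumeration is limited to N ≤ 12 (≈ 35k
  assignments); beyond that only the asymptotic adjustment is available,
  with a warning left to the caller.
* The montage module consumes precomputed ROI field values; it does not
  solve fields (no head models, electrodes, or conductivities).
* The study simulator injects stationary effects; it cannot probe
  time-resolved after-effect decay.
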