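# Methods

This note documents the models and numerical choices behind `pgme`: what
each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Signal preparation

A recording is a tri-axial trunk-acceleration series (AP, ML, V) at 100 Hz.
Walking bouts are cut into consecutive non-overlapping 30-s epochs (3,000
samples); a trailing remainder is discarded, and bouts shorter than one
epoch contribute nothing. Epoch duration is configurable
(`RunConfig.epoch_duration_s`); the test suite frequently uses 10–20 s
epochs to keep simulation studies small, which preserves every structural
property but lowers the number of gait cycles per epoch from ~60 to ~20–40.

**Walking screen.** Visual inspection of epochs is replaced by a
programmatic proxy with two criteria per sliding 3-s subwindow: (a) the
dominant periodogram peak of the V or AP channel lies in a locomotion band
(default 1.2–3.5 Hz) and exceeds the in-band median power by a prominence
factor (default 3), and (b) the count of impact-like peaks (height
≥ 1 SD, separation ≥ 0.3 s) is within ±30% of the step count implied by the
dominant frequency. An epoch is accepted when ≥ 80% of subwindows pass
both. All thresholds live in `ScreenConfig`; screening can be disabled.
On the synthetic generator's default settings the screen accepts ≥ 95% of
gait epochs and rejects ≥ 95% of white-noise epochs (verified over 100
seeds each).

**Velocity and step cycles.** Per channel the epoch mean is removed, the
signal integrated with the cumulative trapezoid rule, and the 3-channel
velocity MEMD-detrended: the residual plus every IMF whose zero-crossing
frequency is below 0.5 Hz is removed, then the channel mean is subtracted
again. The 0.5 Hz cutoff keeps stride (~1 Hz) and step (~2 Hz) components
while removing integration drift. Step-cycle boundaries are local minima of
the vertical velocity (minimum separation 0.3 s, prominence ≥ 0.1 SD);
`cycle_extremum="maxima"` switches the convention, since the source
literature uses both wordings. Cycles lasting outside [0.3 s, 1.0 s] are
marked invalid and contribute nothing downstream.

**Phase windows.** For each valid cycle of duration T and phase p ∈ {0, 20,
40, 60, 80}%, the window is [start + round(p·T/100), +floor(0.10·T))
(minimum one sample), pooled across cycles. Per-cycle durations (not an
epoch average) keep the windows phase-aligned under stride-time jitter; the
five windows are pairwise disjoint because the 20% spacing exceeds the 10%
width.

## Delay embedding

The 6-dim space stacks the three axes at lags 0 and l; the 9-dim space adds
lag 2l. Both are truncated to the common row range j = 0..N−2l−1 so every
9-dim point has a 6-dim counterpart — this, together with the max-norm,
guarantees the match-count inequality n_y ≤ n_x structurally.

The lag l is the flattening point of the average mutual information: the
smallest τ ≥ 1 with AMI(τ−1) − AMI(τ) < 0.01 nats/sample. AMI uses 32
equal-width histogram bins per margin and is averaged over the three axes
before lag selection, because the multichannel embedding needs one common
lag. An AMI *increase* counts as a sub-threshold decrease, so the rule also
fires at local minima; a curve that keeps falling steeply to the end of the
scan falls back to its argmin. The estimator choices (bins, nats,
axis-averaging, max lag 100 samples ≈ one stride) are configurable; none is
fixed by the source material.

## MEMD and coarse-graining

MEMD sifts the multichannel signal with envelopes built over 64
low-discrepancy directions on the unit sphere (Hammersley point set pushed
through the inverse normal CDF and normalized — rotationally uniform and
deterministic). Per direction, projection extrema (plateau midpoints) carry
a natural cubic-spline envelope through the full multichannel signal, with
mirror extension of two extrema at each end; the candidate IMF is the
signal minus the direction-averaged mean envelope, iterated until the
mean-envelope/candidate norm ratio falls below 0.075 on two consecutive
passes or 15 passes elapse. Extraction stops when every projection of the
remainder has fewer than 3 extrema. All constants are config-exposed
decisions, not source facts. The hot path is a numba kernel (Thomas solver
for the natural spline); a scipy reference implementation is kept and the
two agree to ~1e-10 in tests.

Completeness (ΣIMFs + residual = input) holds exactly by telescoping, so
the coarse-grained dynamics d̄_k = Σ_{k'≥k} d_{k'} + residual can also be
computed as input − Σ_{k'<k} d_{k'}. The pipeline exploits this: for scales
1..6 only the first five IMFs are extracted (`max_imfs`), the rest staying
in the residual, which leaves every requested d̄_k exact while halving
runtime. If a decomposition ends naturally with M < k, the scale-k cell is
missing (never zero-filled); subject-level medians skip missing cells and a
cell missing in more than half the epochs stays missing.

## Generalized sample entropy

For an index set (one phase window mapped into the embedded row range),
n_x and n_y are the fractions of ordered pairs (i≠j, |i−j| > Theiler
window, default 0) whose 6-dim and 9-dim rows respectively lie within
max-norm distance r, over an identical denominator; qSaEn =
log_q(n_x) − log_q(n_y) with the Tsallis q-logarithm, natural log within
1e−9 of q = 1. The tolerance r = 0.3 × mean(SD_AP, SD_ML, SD_V) is computed
once per epoch from the raw acceleration and held fixed across scales,
phases and q. Counts are computed once per (scale, phase) and the whole
q grid evaluated from them — exact, since the counts do not depend on q.
Cells with n_y = 0 are undefined and propagate as missing rather than
infinite. A config flag switches match counting from
templates-and-candidates-within-window (default) to templates-in-window
with candidates anywhere.

Two properties worth keeping in mind when reading PGME values:

- **q < 1 is count-scale dependent.** At q = 1 the entropy depends only on
  the ratio n_y/n_x; at q = 0 it is literally n_x − n_y. A manipulation
  that *reduces* local noise raises both counts and therefore typically
  *raises* qSaEn for q < 1 even though the signal became more regular.
  The synthetic faller effect (noise-SD reduction at the 60% phase)
  consequently shows up as *higher* faller PGME at q ≤ 0.5 and a vanishing
  contrast as q → 1 — the phase- and q-localization pattern, not the sign,
  is the robust signature.
- **Phase localization is approximate.** The embedding lag is re-estimated
  per epoch from the AMI of the whole epoch, and MEMD sifting is a global
  operation; a phase-localized change in the signal therefore shifts the
  lag (and the coarse scales) slightly at *all* phases. In matched-cohort
  simulations this produces occasional statistically significant
  off-target cells at coarse scales (see `tests/test_acceptance.py`,
  phase-effect recovery), a genuine property of the estimator rather than
  an implementation artifact.

## Conventional gait features

Acceleration SDs, stride regularity (unbiased autocorrelation at the stride
lag, peak searched within ±10%), stride time/frequency and their SDs (from
alternate cycle boundaries), harmonic ratio (first 20 stride harmonics;
even/odd for AP and V, odd/even for ML), index of harmonicity (fundamental
power over the first 6 harmonics; step frequency as fundamental for AP/V,
stride frequency for ML), Welch-spectrum descriptors (5-s segments, 50%
overlap; dominant 0.5–3 Hz peak, normalized amplitude, half-height width,
log–log slope over 0.5–10 Hz, central-98% band), low-frequency percentage
(power below 0.7 Hz within 0–10 Hz), and largest Lyapunov exponents
(Rosenstein and Wolf, dim 5, AMI lag, raw and per-stride). Features needing
a body model (walking speed, step length and their variabilities) are out
of scope. All spectral conventions are configurable; the subject-level
aggregate is the median across epochs, mirroring PGME.

Numerical notes: the Rosenstein estimator excludes neighbor pairs closer
than 1e−8 × attractor extent, otherwise exact recurrences of periodic
signals make the divergence curve track floating-point noise; its default
fit window is the first half stride, while oracle tests on Lorenz-63 use a
0.5–1.5 time-unit window past the initial transient (estimate within ~11%
of the classical 0.906). Wolf's trajectory-following uses 0.1-s evolution
steps and a separation band of [1e−3, 0.1] × extent with
nearest-in-band replacement.

## Prediction pipeline

NIPALS PLS1 (weight–score–loading iteration with deflation, tolerance
1e−10, ≤ 500 inner iterations) is implemented in-package and verified
against closed-form least squares at full rank and against
`sklearn.cross_decomposition.PLSRegression` at reduced rank. An LDA with
pooled covariance runs on the latent scores (posterior threshold 0.5). The
component count (≤ 10) is selected by internal 10-fold CV with the
one-standard-error parsimony rule — the smallest count whose error is
within one SE of the minimum; plain argmin systematically inflates the
latent space on noise features. Feature ranking uses target-projection
loadings (|X′t_tp|/t_tp′t_tp along the normalized regression vector), ties
broken alphabetically. Backward elimination drops, per round, the feature
whose removal minimizes the internal CV error (one shared fold assignment
per round so candidate errors are paired) and returns the subset at the
global error minimum of the trace.

Holdouts are stratified and pair-preserving: matched pairs move together,
so class balance is exact in every split. Performance is the mean of
per-holdout confusion rates with 95% percentile-bootstrap CIs (1,000
resamples of the repetition-level values). For AICc a classifier
likelihood must be chosen: the package uses the binomial log-likelihood of
the held-out LDA posteriors with k = components + 1 parameters — an
interpretation, flagged here because AIC for discriminant classifiers is
not uniquely defined. Relative likelihood exp((AICc_min − AICc)/2) < 0.05
marks a significantly worse model. Group contrasts are two-sided Wilcoxon
rank-sum tests per tensor cell with Benjamini–Hochberg correction across
all tested cells; cells with fewer than two finite values per group are
excluded from the correction count.

## Synthetic gait generator

Step intervals are T_i = (1/f_step)(1 + ε_i), ε_i ~ N(0, stride_cv²) with
f_step = 2 Hz and stride_cv = 0.03. Each axis is a 6-harmonic Fourier
series in *stride* phase (two steps), with AP/V dominated by even
(step-rate) harmonics and ML by odd ones; the even V harmonics sit at phase
3π/2 so the integrated vertical velocity has minima at cycle starts, making
the generator's boundaries the oracle for cycle detection. A damped
12 Hz oscillation (decay 0.05 s) at every cycle start mimics heel strike
(full on V, half on AP). Gaussian noise with baseline SD 0.15 m/s² is
modulated by a five-bin step-phase profile; the "faller" effect multiplies
the bin containing the 60% phase by effect_delta (default 0.5, i.e. locally
*less* irregular). Cohorts are matched pairs sharing a demographic draw;
per-subject lognormal random effects perturb step frequency (4%), noise SD
(15%) and harmonic amplitudes (10%). Demographics are uninformative noise
by default so the classifier's signal comes from the gait features.

What the generator does *not* emulate: non-stationary bout structure,
turns and micro-breaks, sensor tilt/calibration error, non-Gaussian sensor
noise, and any biomechanical coupling between axes beyond the shared phase.
Passing tests therefore demonstrate the estimator pipeline's correctness
and sensitivity under controlled conditions, not clinical validity on real
accelerometry.

## Problem sizes used in tests

Simulation studies run at reduced sizes chosen to keep the default suite
fast while preserving the tested property: 10-s epochs (≈ 20 cycles) and
8–16 MEMD directions in pipeline-level tests, 20 matched pairs × 5 epochs
for cohort replicates (20 effect + 10 null), 100 signals/epochs for the
completeness and structural checks, and 50 holdout repetitions (scaled
from 500) in the PLS protocol. `scripts/acceptance.py` re-runs the same
computations from scratch at these sizes.

## Known limitations

- With strong local noise the 9-dim match count can hit zero, leaving
  cells undefined; this is reported as missing, but it means very
  irregular epochs contribute sparser tensors.
- The per-epoch tolerance r couples all cells to the epoch's overall SD, so
  group manipulations that change total variance shift every cell slightly.
- MEMD mode mixing can split near-cutoff content (~0.5 Hz) between kept and
  removed IMFs during detrending.
- Backward elimination is O(p²) model fits and impractical for the full
  630-cell PGME tensor; rank-based pre-screening (TP-loadings) is the
  intended route for large p.
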