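# pgme — phase-dependent generalized multiscale entropy of walking

`pgme` analyses tri-axial trunk-acceleration recordings of walking (lower-back
inertial sensor, AP/ML/V axes, 100 Hz) and asks whether the *irregularity* of
the gait dynamics — resolved by temporal scale, by phase of the step cycle,
and by entropic order q — distinguishes older adults who go on to fall from
matched non-fallers. It is aimed at movement-science and wearable-sensing
researchers who want a phase-resolved alternative to conventional multiscale
entropy, together with the standard trunk-accelerometry feature battery and a
matched-pair classification protocol.

## The measure

A 30-s walking epoch is embedded in two nested delay spaces built from the
three acceleration axes at lags 0, l, 2l:

    X_j = (a_j^AP, a_j^ML, a_j^V, a_{j+l}^AP, a_{j+l}^ML, a_{j+l}^V)               (6-dim)
    Y_j = (X_j, a_{j+2l}^AP, a_{j+2l}^ML, a_{j+2l}^V)                              (9-dim)

with l chosen per epoch from the flattening point of the average mutual
information (decrease < 0.01 nats/sample). The embedded dynamics are
decomposed by multivariate empirical mode decomposition (MEMD) and
coarse-grained at scale k as the partial sum d̄_k = Σ_{k'≥k} d_{k'} + residual,
so k = 1 is the original signal and larger k progressively low-pass versions.
On each coarse scale, the generalized sample entropy

    qSaEn = log_q(n_x) − log_q(n_y),      log_q(n) = (n^(1−q) − 1)/(1 − q)

is evaluated from the fractions n_x, n_y of point pairs within tolerance
r = 0.3·SD (mean SD over the three axes) under the max-norm, restricted to
pooled windows covering 10% of the step time after 0, 20, 40, 60 and 80% of
each step cycle (cycles = intervals between consecutive vertical-velocity
minima). At q = 1 this is the ordinary sample entropy ln(n_x/n_y); q < 1
re-weights the count scale so phase-localized regularity changes become
visible. The result is a 6 (scales) × 5 (phases) × 21 (q ∈ [−1, 1]) tensor
per epoch; subjects are summarized by the cell-wise median over their epochs.

Fall prediction uses NIPALS partial least squares with an LDA on the latent
scores, Z-scored features, target-projection loadings for feature ranking,
backward feature elimination, stratified pair-preserving holdouts with
percentile-bootstrap CIs, and AICc model comparison. Faller vs non-faller
tensor contrasts use Wilcoxon rank-sum tests per cell with Benjamini–Hochberg
FDR control.

Because no public trunk-acceleration fall cohort ships with the package, a
seeded synthetic-gait generator (Fourier gait waveform phase-locked to
jittered step cycles, heel-strike transients, phase-binned noise) produces
matched cohorts with controllable phase-localized irregularity differences;
it is the substrate for all tests.

## Worked example

```python
import numpy as np
from pgme import (GaitSimParams, simulate_epoch, StepCycleSet,
                  EntropyConfig, pgme_epoch)

epoch, boundaries = simulate_epoch(GaitSimParams(seed=11))
cycles = StepCycleSet(boundaries=boundaries, fs=epoch.fs)
cfg = EntropyConfig(n_dirs=8, ami_max_lag=40)
tensor = pgme_epoch(epoch, cycles, cfg)
print("lag:", tensor.meta["lag"], " r:", round(tensor.meta["r"], 3))
for phase in (0, 20, 40, 60, 80):
    print(f"phase {phase:2d}%  SampEn(k=1,q=1) =",
          round(tensor.cell(1, phase, 1.0), 3))
```

prints

```
lag: 10  r: 0.131
phase  0%  SampEn(k=1,q=1) = 2.757
phase 20%  SampEn(k=1,q=1) = 2.897
phase 40%  SampEn(k=1,q=1) = 3.091
phase 60%  SampEn(k=1,q=1) = 3.016
phase 80%  SampEn(k=1,q=1) = 3.045
```

i.e. the per-phase conditional irregularity of the trunk dynamics at the
original scale — around e^3 ≈ 20 times more 6-dim than 9-dim matches in the
mid-cycle windows; q < 1 columns of the same tensor re-weight these values
by absolute match counts rather than their ratio.

A shell workflow is available through the `pgme` command
(`simulate`, `extract`, `predict`, `compare`, `report`); run
`pgme simulate --pairs 2 --epochs 1 --out demo/` then
`pgme extract --input demo/ --out out/` for a quick tour.

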