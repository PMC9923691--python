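# Methods

## The model

The object of analysis is an item-level ERP dataset: one subject-averaged
epoch per word, `items × sensors × timepoints` (µV), on a −100…920 ms
epoch sampled at 200 Hz (205 samples; windows are inclusive at both ends,
so 300–500 ms covers 41 samples). The working hypothesis is linear: at
each timepoint the sensor pattern evoked by word *i* is a weighted sum of
the word's embedding axes,

```
S[i, s, t] = Σ_d F[i, d] · B_t[d, s] + ε
```

Encoding estimates `B_t` by ridge regression (per timepoint, per fold)
and asks how much held-out variation it explains; decoding inverts the
direction and asks how much of the word's position in (compressed)
embedding space is recoverable from `S`. All claims are cross-validated:
10 folds built by a seeded shuffle followed by contiguous blocks, so fold
sizes differ by at most one item.

Scoring uses the signed squared correlation `sign(r)·r²` across held-out
items. It preserves the direction of fit (anti-correlated predictions
score negatively instead of being rewarded) and is invariant to the scale
and offset of predictions, which is why per-fold target/feature
standardization never affects scores. Correlations with a constant vector
are defined as 0 — degenerate but harmless (it is the value such scores
converge to under the null).

## Synthetic data: what is emulated, and what is not

The generator produces the full input bundle from one master seed
(expanded into independent child seeds per component, so every artifact is
bit-identically reproducible):

* **Embeddings** `F = loadings · directions + noise + mean`: `k_true = 8`
  latent factors with geometrically decaying variances (ratio 0.8 per
  factor, normalized to sum to `k_true`), loading columns constructed
  exactly orthogonal in-sample, mixed into `dims = 50` axes through
  orthonormal directions, plus isotropic Gaussian noise scaled so
  factor-explained variance / noise variance = `factor_snr` (default 4),
  plus a shared mean offset (2× the per-row sd) along a direction
  orthogonal to all factors. The decaying spectrum makes the factors
  identifiable as individual kernel-PCA components (equal variances would
  leave the factor subspace rotationally ambiguous); the mean offset
  concentrates row norms, as in real distributional embeddings, so the
  cosine kernel is an undistorted image of the factor structure. With
  these defaults each planted factor matches one of the first eight
  cosine-kernel-PCA components at |r| ≈ 0.93–0.99 on a 300-word sample.
* **ERPs**: `data[i,s,t] = (F[i]·mixing[:,s]) · profile[t] + N(0, noise_sd)`.
  The mixing wires a chosen factor subset (default factors 1–3) into the
  sensors; the temporal profile is an N400-like raised-cosine bump over
  300–500 ms, peak 1 at 400 ms, sampled so that the window endpoints are
  interior points of the taper — every in-window sample carries signal,
  every sample outside the closed window is exactly zero. Subject-level
  variability is not simulated: the modeled object is the per-word
  subject-averaged ERP, and `noise_sd` is the residual noise surviving
  averaging. Its default (2.0 µV against a unit-gain forward model) is
  calibrated so window encoding scores land near 0.05–0.1 at the
  300-word/28-sensor scale — a plausible range for this kind of data, not
  a fit to any particular dataset.
* **Taxonomy**: recursive balanced spectral bisection of a blended
  distance, `fidelity` parts cosine distance and `1 − fidelity` parts
  seeded random distance. All leaves sit at (near-)equal depth, as in a
  category system, so the leaf-to-leaf edge count measures the level at
  which two words separate; agglomerative linkage was rejected because
  its strongly unbalanced trees make edge counts reflect leaf depth
  rather than pairwise similarity (Spearman with cosine similarity ~0.1
  at fidelity 1, vs ~0.4 for the balanced construction).
* **Covariates**: log₁₀ frequency ~ N(1.5, 1) counts-per-million style,
  concreteness ~ N(4.5, 1) on a 1–7 rating-like scale; concreteness is
  correlated 0.5 with the leading factor by default (concreteness is the
  classic first latent dimension of noun semantics), and any covariate
  can be tied to any factor at a requested coefficient.

Two preset shapes mirror the study designs this emulates: `english`
(960 words, 28 sensors) and `german` (150 words, 64 sensors).

What the generator does **not** emulate: continuous raw EEG, ocular/other
artifacts, filtering, volume-conduction-realistic topographies, temporally
or spatially correlated noise, subject sampling. Passing tests therefore
demonstrate that the *pipeline* recovers planted structure and calibrates
under its nulls — not that real data meet the linearity or noise
assumptions.

## Statistics

* **Bootstrap CIs**: percentile method on the mean, resampling the 10
  folds with replacement (default 10 000 resamples, seeded). Caveat: at
  n = 10 the percentile method is anti-conservative — its measured
  coverage for a nominal 95% interval on Gaussian values is ≈ 90%, and a
  nominal 99.375% interval excludes a true null in ≈ 3% of datasets. The
  method is kept because it is the field's convention for fold CIs; the
  CIs should be read as descriptive, not exact.
* **Wilcoxon signed-rank** (window scores and paired model differences
  against 0): zero differences dropped; for n ≤ 25 the exact two-sided p
  comes from the complete null distribution of the positive-rank sum
  (dynamic programming over sign assignments, tie-aware via doubled
  ranks — identical to enumerating all 2ⁿ patterns); beyond that, normal
  approximation with continuity and tie corrections. At 10 folds the
  smallest attainable two-sided p is 2/1024 ≈ 0.002.
* **Wilcoxon rank-sum** is available as the unpaired variant of the model
  comparison (exact for pooled n ≤ 20 without ties). The paired
  signed-rank on per-fold differences is the default, since the folds are
  shared between the two models being compared.
* **Multiple comparisons**: handled through the CI level, `1 − α/k`
  (99.375% for 8 components at family α 0.05), not through p-value
  adjustment. Time-resolved CIs are uncorrected 68%, display-only.

## Numerical and design choices

* Ridge is solved in closed form via Cholesky on the standardized
  features; when features outnumber training items the dual (kernel) form
  `Xᵀ(XXᵀ + λI)⁻¹y` is used — identical predictions, cheaper. The default
  penalty is 1.0 on standardized features, never tuned on test items;
  scaling is always learned on the training fold only (a zero-variance
  feature becomes an all-zero column and gets a zero weight).
* Sensor aggregation for encoding scores: correlation per sensor across
  held-out items, sign-squared, then averaged over sensors (default); a
  flattened items × sensors variant is available. Which a given study
  used is often underspecified; per-sensor is the default because it
  weights sensors equally regardless of amplitude.
* Kernel PCA: double-center the kernel, eigendecompose, scores =
  eigenvector · √max(eigenvalue, 0); columns re-centered to remove
  null-space numerical drift; column signs fixed by making the
  largest-magnitude entry positive; ties in top-word rankings break by
  word order. The decomposition is fitted once on all items before
  decoding — the mild target-side train/test leakage this implies is a
  deliberate replication of common practice and is flagged here.
* Taxonomy features (a word's path similarity to every word in the
  lexicon) are stimulus properties, computed once from the full lexicon
  identically for train and test items; no neural data leaks through
  them.
* Decoder patterns: `zscore` standardizes the raw backward weights per
  component across electrodes; `haufe` first maps weights to activation
  patterns (feature covariance × weights). Normalized backward weights
  and forward-model patterns answer different questions and are sometimes
  conflated; both are shipped, default `zscore`. Patterns come from a
  decoder refit on all items (display only, never scored).

## Problem sizes used by the test suite

Unit and acceptance tests run the 300-word / 28-sensor / 205-timepoint
fixture (10 folds) for recovery and null checks, the 40-word / 10-dim /
8-sensor fixture for the primal–dual identity, and the 150-word /
64-sensor German-shaped preset for the end-to-end pipeline; seed-sweep
properties use 20 fixtures. These sizes were chosen as the smallest at
which the estimated quantities are stable.

## Known limitations

* Fold-level inference inherits cross-validation dependence: the 10 folds
  share one dataset, so fold scores are positively correlated, fold-level
  signed-rank tests are mildly anti-conservative in the presence of any
  dataset-level idiosyncrasy, and fold-bootstrap CIs under-cover at n = 10
  (see above). On null fixtures this shows up as a false-positive rate of
  roughly 3–20% depending on the statistic — consistent with what is known
  about CV-based inference generally, and worth keeping in mind when
  reading per-component significance flags.
* Kernel-PCA components beyond the planted ones are not pure nulls: the
  residual of each planted factor not captured by its matching component
  leaks into later components, which therefore carry traces of genuinely
  decodable signal.
* The linear forward model and iid Gaussian sensor noise are idealized;
  scores on real data depend on preprocessing choices that are out of
  scope here.
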