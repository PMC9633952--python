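# Methods

## Pipeline model

`eegselect` treats subject-specific channel selection as a wrapper search:
the figure of merit for a channel subset is the cross-validated accuracy
of the very classifier that will be deployed, not a proxy statistic. The
pipeline stages, in execution order:

1. **Band-pass 8–30 Hz** (third-order Butterworth, applied forward and
   backward). The mu and beta rhythms that carry ERD both fall inside this
   band. Zero-phase filtering is a deliberate choice: the analysis is
   offline, and the criterion is variance-based and therefore insensitive
   to phase, so the two-pass scheme costs nothing and avoids group delay.
   "Order 3" refers to the one-direction design; the effective magnitude
   response is |H(f)|².
2. **Fixed-window segmentation** relative to trial onset (presets `iv1`
   2–6 s, `iii-iiia` 3–6 s, `iii-iva` 0–3 s, `iv-2a` 3–6 s). Seconds are
   converted to samples by round-half-up; windows are half-open and
   0-based so fixtures are bit-stable.
3. **CSP features.** Per-trial covariance is trace-normalized
   `X Xᵀ / tr(X Xᵀ)`; trials are *not* mean-centered (band-passed signals
   are zero-mean, and the uncentered convention makes the Gram-matrix fast
   path below exactly equal to the naive computation). The whitening
   transform is P = diag(λ)^(−1/2) Uᵀ — the exponent −1/2 is forced by the
   contract P C_c Pᵀ = I, which the rest of the decomposition (Λ_a + Λ_b =
   I) depends on. Features are log-variances of the projections on the
   first and last `m_pairs` columns of W = PᵀV (columns sorted by
   descending Λ_a).
4. **Criterion.** Stratified 10-fold CV; CSP is refitted on each training
   fold so no test-trial statistics leak into the filters. The classifier
   is an RBF-SVM with C = 1 and gamma = 1/(n_features · feature variance)
   — ordinary defaults, exposed in `CriterionConfig`. The fold partition
   is drawn once per evaluator from its seed and reused for every subset,
   so J values of different subsets are paired comparisons; evaluations
   are memoized by subset.
5. **Floating search.** Exclusion picks the removal maximizing J
   (ties: remove the lowest acquisition ordinal — later channels survive
   ties); conditional inclusion re-adds an excluded unit only on *strict*
   improvement over the per-size record, which prevents oscillation. The
   per-size record is monotone by construction and is the artifact from
   which the accuracy-vs-k curve and the final subset are read; final ties
   across sizes resolve to the fewest channels. Termination: an exclusion
   reaching `k_min` (default 2, the smallest subset CSP accepts), or no
   legal move; a `max_steps` cap (50·d) guards against pathological
   criteria and flags the trace non-terminated instead of looping.
6. **Modified search.** Atomic moves are channel units: left–right mirror
   pairs from the 10-20 label rule (odd ↔ next even digit, same prefix),
   validated against scalp coordinates when available and completed by
   mutual-nearest coordinate mirroring (tolerance: 10% of the montage's
   coordinate range); midline/unmatched channels are singleton units and
   remain individually selectable. Sizes skipped by pair moves simply have
   no record entry; reports leave them absent rather than interpolating.

## Computational shortcut

CSP fitting and log-variance features depend on the data only through the
per-trial Gram matrices R_t = X_t X_tᵀ. The evaluator computes R_t once on
the full montage; a subset's covariance is a renormalized sub-block and a
projected variance is wᵀR_t w / n_samples. A full 16-channel SBFS run
(~250 criterion evaluations × 10 folds) therefore takes seconds on one
CPU. This is an exact reorganization, checked in the tests against the
stepwise oracle (explicit projection, variance, log).

## Synthetic generator

`simulate_mi` emulates the minimal physiology the method exploits. Each
channel is an independent band-limited (8–30 Hz) Gaussian source; on a
left-hand trial the planted right-hemisphere channels have their source
variance multiplied by (1 − erd_depth), and symmetrically for right-hand
trials; sources are then mixed by A = I + mixing_strength·M with
M = (G + Gᵀ)/(2√n) fixed per seed. Labels alternate deterministically;
everything else derives from the seed.

Defaults (the study conditions): 16-channel all-paired sensorimotor grid,
planted channels C3/CP3 (left) and C4/CP4 (right), 60 trials per class,
fs = 100 Hz, 3 s trials, erd_depth = 0.8, mixing_strength = 0.3,
noise_sd = 1. fs and trial length match the downsampled public MI
recordings this pipeline targets; the mixing normalization puts
per-channel leakage variance at ≈ mixing_strength²/2 ≈ 5% of the direct
signal, a mild volume-conduction level; erd_depth = 0.8 is a strong,
unambiguous effect suitable for verifying recovery behavior. One second
of padding per trial edge is generated, filtered and discarded so
retained samples are stationary.

What the generator does *not* emulate — and hence what passing tests do
not show about real EEG: oscillatory structure beyond band-limited noise,
trial-to-trial ERD variability, artifacts (EOG/EMG), non-stationarity,
realistic forward-model mixing. Two consequences matter for interpreting
results at the defaults. First, because the variance suppression is
deterministic and each 3 s trial contains ≈130 effective samples, the
per-trial log-variance separation at erd_depth 0.8 is ≈13σ: CV accuracy
saturates at 100% for any subset containing lateralized signal, the
accuracy-vs-k record ties across sizes, and the fewest-channels tie rule
then selects a 2-channel subset (the acceptance script reports exactly
this). Real recordings, with their large trial-to-trial variability, do
not saturate. Second, on permuted labels the features still carry the
true-class cluster structure, so the null distribution of CV accuracy is
wider than a Binomial(n, ½) band and has the well-known below-chance
anti-learning tail. Weaker settings (e.g. erd_depth ≈ 0.25 with stronger
mixing, as in the README example) produce non-degenerate accuracy-vs-k
curves where selection visibly beats the full montage.

## Numerical choices

- Ridge ε = 10⁻¹⁰·tr(C_c) added before the composite eigendecomposition
  so rank-deficient subsets (duplicated or silent channels) remain
  decomposable; eigenvalues are clipped below at ε.
- Eigenvector signs are fixed (first non-negligible entry positive) and
  Λ_a sorting is descending, making W deterministic; with that, traces
  serialize to byte-identical JSON across runs of the same seed.
- Zero-variance projections clamp at the smallest positive double before
  the log and emit a warning rather than failing a whole search.
- All randomness (generator, fold shuffling) flows through explicit
  integer seeds; there is no global RNG state.
- Subsets are canonicalized (sorted, deduplicated) before evaluation, so
  the criterion is exactly invariant to subset ordering and memoization
  keys on the set, not the sequence.

## Problem sizes in the test suite

The suite and the acceptance script run entirely on generated data:
16 channels × 120 trials × 300 samples for the study conditions (ten
seeds of both search modes run in under a minute thanks to the Gram-matrix
path), 2⁶–2⁸ exhaustive enumerations for the search oracles, and ≤8
channels for brute-force comparisons. EDF reading is verified against a
minimal independent EDF writer implemented in the test helpers; GDF
parsing is exercised for error handling only, since no independent GDF
writer is available in the toolchain.

## Known limitations

- Binary classification only (no one-vs-rest CSP); no artifact handling;
  no re-referencing or downsampling.
- SBFS is greedy: the per-size record is a lower bound on the exhaustive
  per-size optimum (asserted in the tests), not a guarantee of it.
- The modified search's pair derivation is a generalization from 10-20
  naming plus geometry; exotic montages without either standard names or
  coordinates degrade to channel-wise behavior (all singletons).
- `best_subset` on a saturated criterion is dominated by the tie rule;
  report the full accuracy-vs-k curve, not just the argmax, whenever the
  criterion is near its ceiling.
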