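# Methods

## The estimator

A scan is an M × N matrix X of ROI signals (M time points, N ROIs).
Each column is centered and scaled to unit Euclidean norm, after which
the order-1 network is `R₁ = XᵀX`, the ordinary Pearson correlation
matrix.  Higher orders iterate the correlation: the rows of `Rₙ₋₁` are
treated as new signals and correlated.  Because `Rₙ₋₁` is symmetric,
the step has the closed form

    Rₙ = D^{-1/2} M D^{-1/2},   M = Rₙ₋₁ C Rₙ₋₁,   D = diag(M),

where `C = I − E/N` is the symmetric idempotent centering matrix
(`M = (Rₙ₋₁C)(Rₙ₋₁C)ᵀ` since C² = C, i.e. the Gram matrix of the
centered rows).  The centering divisor is N, the ROI count — the only
dimensionally consistent choice for an N × N matrix — and the
implementation is verified against a brute-force rows-as-signals
Pearson oracle at 1e−10 on random inputs, which confirms the two
formulations of the step (explicit row standardization vs. the matrix
form) coincide.

Empirically the sequence converges: deltas `max|Rₙ − Rₙ₋₁|` shrink to
zero and the off-diagonal entries approach ±1.  Convergence is declared
when the delta drops below `tol` (default 1e−6), capped at `max_iter`
iterations (default 30, after which Gaussian scans of the default shape
have long converged — typically at order 13–16).  Non-convergence
within the cap is reported, not raised.  A "binariness" score — the
mean off-diagonal |r| — instruments the approach to the ±1 limit; it is
a diagnostic of this package, not an estimator property.

### Numerical policy

- After every step the matrix is symmetrized, entries within ~50 ulps
  of ±1 are snapped to ±1 exactly, values are clipped to [−1, 1] and
  the diagonal is forced to 1.  This makes the exact-arithmetic
  identities (sign-matrix fixed points, the N = 2 closed form
  `[[1,r],[r,1]] → [[1,−1],[−1,1]]`) survive floating point; the snap
  threshold is ten thousand times smaller than any tolerance used to
  compare matrices, so it cannot mask genuine structure.
- The rescaling is computed as `M / sqrt(outer(d, d))` (division, not
  multiplication by an inverse square root), which lands closed-form
  cases exactly on ±1.
- A diagonal entry of M at or below 1e−12 means the corresponding row
  was constant and its correlation is undefined.  The default policy
  raises a degenerate-signal error naming the node and the order; the
  alternative `"zero"` policy zero-fills the node's off-diagonal
  entries and records it in `degenerate_nodes`.
- An off-diagonal converged entry at exactly 0 is reported as-is; the
  ±1 limit is an empirical observation, not a guarantee.

## Diagnostics

- **Rank**: the count of singular values above `rel_tol · σ_max`
  (default 1e−8).  Along the sequence the rank is non-increasing (the
  rank of a product is bounded by the rank of each factor); a violation
  in floating point raises a warning, not an error.
- **Sign flips**: per consecutive pair, the number of upper-triangle
  entries whose sign differs (0 counts as its own sign).  Late in the
  iteration this drops to zero; no threshold is asserted for how few
  flips are "few".
- **Fixed-point residual**: `max|step(R) − R|`.  Any sign matrix
  `s sᵀ` with both signs present is an exact fixed point
  (`M = (sᵀCs) · s sᵀ` with `sᵀCs = N − (Σs)²/N > 0`), which the tests
  verify constructively.

## Classification protocol

Edge features are the strict upper triangle in row-major order.  On
each training fold a two-sample t-test (pooled variance by default;
Welch behind a flag) keeps edges with p below the working threshold;
the default threshold grid is {0.05, 0.01, 0.005, 0.001}.  A linear SVM
with C = 1 is fitted on the selected edges, and a one-dimensional
logistic regression on the training decision values (Platt-style
sigmoid, unit ridge so the separable case stays finite) maps margins to
probabilities; scans are called positive at probability 0.5.  An empty
selection falls back to the training majority-class probability, with a
warning.

Cross-validation is at the subject level: subjects (stratified by their
majority scan label, ties to the positive class) are shuffled by the
seed and dealt round-robin into k folds, so fold sizes differ by at
most one subject and no subject's scans straddle the boundary.  Scans
are scored individually; pooled test predictions over the outer folds
give the reported TP/TN/FP/FN and ACC/SEN/SPE (a zero denominator
yields NaN plus a flag).  Selection scope is per-training-fold by
default to avoid leakage; a `"global"` scope (selection once on all
scans) exists for feature-count reporting.

Late fusion combines the order-1 and an order-n classifier's
probabilities as `λO₁ + (1−λ)O₂`.  Within each outer training fold, λ
is chosen from {0.1, …, 0.9} by an inner subject-level 5-fold CV of the
full pipeline (selection and both classifiers refitted per inner fold);
the highest mean inner accuracy wins, ties going to the λ nearest 0.5
and then to the smaller value.  Both classifiers are then retrained on
the whole outer training fold before scoring the test fold.

## Synthetic cohorts

Scans are multivariate Gaussian draws (Cholesky factor of the target
correlation), optionally mixed per time point with an inverse-chi-square
scale for a Student-t option (the correlation estimators are
moment-based, so Gaussianity makes the planted correlations exact
population targets), optionally AR(1)-filtered per ROI and
re-standardized.  The target correlation is block-diagonal compound
symmetry — blocks of 4 ROIs at ρ = 0.3 by default — and the positive
group additionally shifts 30 between-block edges by Δρ = 0.3 (drawn
deterministically from the cohort seed).  Targets that lose positive
definiteness are repaired by eigenvalue clipping and re-normalisation,
with a warning.

Default cohort shape: N = 116 ROIs × M = 137 time points, 72 subjects
per group, one scan each — the shape of a typical AAL-parcellated
resting-state cohort.  The `adni` preset gives subjects 1–3 scans each
(mixed-scan cohort, ≈288 scans / 144 subjects); the `hcp` preset uses
100 ROIs × 1,200 time points with four sessions per subject.  Scan
draws are keyed by (cohort seed, group, subject, scan), so datasets are
fully reproducible and subjects are independent.

What the generator does *not* emulate: hemodynamics, drift, motion,
spatial structure, site effects, or non-stationarity.  Passing tests
therefore show that the estimator and protocol behave as described on
data whose second-order structure is known exactly — not that any
particular accuracy would be attained on real fMRI.

## Problem sizes used by the checks

The convergence and chance-level checks run at the full default shape
(137 × 116; ten cohort seeds for the chance-level mean).  The
order-wise downtrend check uses a reduced cohort — 60 ROIs × 80 time
points, 36 subjects per group, 20 planted edges — which preserves the
qualitative regime (edges ≫ scans, strong low-order signal) at a
fraction of the cost; oracle-equivalence, fixed-point, rank and
closed-form checks use many small random matrices (N ≤ 50).

## Known limitations

- Convergence of the matrix sequence is instrumented, never proved;
  `max_iter` is a pragmatic cap, and the binary ±1 limit is an
  empirical regularity of generic inputs.
- Platt calibration is fitted on the same training scans as the SVM
  (no inner calibration split); probabilities are therefore slightly
  optimistic, which is immaterial for threshold-0.5 accuracy but worth
  knowing before interpreting them as risks.
- The t-test treats scans as exchangeable within groups; repeated scans
  of one subject violate independence.  Subject-level folding protects
  the train/test boundary, but within-fold selection still sees
  correlated scans, as in the protocol it mirrors.
- With ~N²/2 features and at most a few hundred scans, selected-feature
  counts at loose thresholds include many false positives; they are
  reported as counts, not as discoveries.
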