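# Methods

## Instruments and scoring

Four instruments are shipped as `QuestionnaireSpec` configuration
(`moodlatent.questionnaires`), editable via YAML:

| Instrument | Items | Scale | Total | Bands |
|---|---|---|---|---|
| MZ | 6 | 1–7 | none (vector instrument) | none |
| ASRM | 5 | 0–4 | item sum, 0–20 | cut-off 5.5 (integer totals ≥ 6 are "above manic-episode cut-off") |
| QIDS | 16 | 0–3 | sum of 9 domain maxima, 0–27 | ≤5 normal, 6–10 mild, 11–15 moderate, 16–20 severe, 21–27 very severe |
| GAD-7 | 7 | 0–3 | item sum, 0–21 | ≤4 minimal, 5–9 mild, 10–14 moderate, 15–21 severe |

The QIDS domain grouping follows the standard QIDS-SR16 convention: sleep
= max(items 1–4), appetite/weight = max(items 6–9), psychomotor =
max(items 15–16), the remaining seven domains are single items. The
grouping is data, not code: an alternative grouping is just a different
spec. The analysis matrix for QIDS uses the 9 domain scores, not the 16
raw items.

## Preprocessing

Records with any missing item are deleted whole (listwise deletion); no
imputation is performed. Duplicate (participant, date, instrument) records
keep the last occurrence with a warning, treating resubmission as
correction. Per-participant centering subtracts each participant's own
per-item mean over their whole history, removing individual reporting
bias; it is exactly invertible (`reconstruct_raw`) and idempotent to
1e-10. Items are *not* scaled to unit variance — components should weight
items by their actual variability on the shared Likert scale. Participants
with a single record center to an all-zero row and are retained by default
(`min_records_per_participant=1`). Dates are provenance only; records are
treated as exchangeable samples, with no resampling or time alignment.

## Sparse PCA

The estimator (`moodlatent.latent.SparsePCA`) controls sparsity through
the cardinality k directly, because "how many items may contribute" is the
quantity an analyst reasons about and it makes correctness checkable
against exhaustive subset enumeration. The solver:

1. runs hard-thresholded power iteration `w ← normalize(top_k(S w))` from
   several starts — the dense leading eigenvector, its k-thresholded
   version, every coordinate axis (which guarantees the best single item
   is always considered), and `restarts` random unit vectors (default 8);
2. takes the support of the best converged iterate and replaces the
   loading by the exact leading eigenvector of `S[support, support]`, so
   the achieved variance is exactly that submatrix's leading eigenvalue.

The reported support is padded to exactly k indices even when the optimal
loading is zero on some of them (e.g. a dominant-diagonal covariance with
k = M), so component cardinality is a configuration invariant. For the
questionnaire dimensions involved (M ≤ 21) the multistart scheme recovers
the global k-sparse optimum; the test suite verifies equality with
brute-force enumeration over all C(M,k) submatrices for M ≤ 7 across 100
random PSD matrices. `solver="l1"` provides the soft-thresholded
(L1-penalized) variant with the penalty bisected (60 iterations) until the
iterate has the target number of nonzeros.

Convergence: relative change of achieved variance below `tol=1e-9`, or
`max_iter=1000`. Sign convention: the largest-magnitude entry of every
loading is positive (ties: lowest index). Equal-variance ties in support
selection resolve to the lowest item indices via stable argsort. Repeated
fits with the same `random_state` are bit-identical.

**Deflation** is projection deflation of the data matrix,
`X ← X(I − wwᵀ)`, not Hotelling deflation of the covariance: scores remain
computable against the original X and the deflated covariance cannot
acquire spurious negative eigenvalues. Scores reported in a `ComponentSet`
are always against the *undeflated* matrix.

**Variance accounting.** Sparse components are correlated, so naive
per-component variances double-count. Cumulative explained variance uses
successive orthogonalization: QR-factorize the score matrix `T = X Lᵀ` and
attribute `R[i,i]²/(N−1)` to component i. This is conservative
(order-dependent, matching fit order), reduces exactly to eigenvalue
ratios for dense PCA loadings, and is bounded by the dense cumulative
variance at every index.

**Choosing k.** `cardinality_path` reports, at any deflation stage, the
best achievable variance for every k = 1..M (monotone, reaching the dense
leading eigenvalue at k = M). Defaults: 3 components with k = 2 each —
appropriate for 5–9-column instruments, configurable per component — or
`cardinality="auto"`, which picks the smallest k reaching 90%
(`auto_variance_fraction`) of the dense leading eigenvalue at that stage.

## Cohort comparison

Scores are compared per component between cohorts only when every cohort's
sparse supports coincide as sets (components may appear in different
order); otherwise the components measure different item clusters and the
comparison is skipped. Components are matched across cohorts by support
set, labelled by their support items, and ordered as in the first cohort.
By default each cohort is scored on its own fitted loadings
(`loadings_mode="per_cohort"`); `"pooled"` applies the first cohort's
loadings everywhere. Both are defensible; the default respects each
cohort's own weighting while the shared supports keep the components
comparable.

* **KDE**: Gaussian kernels, Silverman's rule-of-thumb bandwidth
  (configurable), evaluated on 512 points spanning the sample range ± 3
  bandwidths, renormalized to trapezoid integral 1 (to 1e-6).
* **KS test**: `D = sup |ECDF_a − ECDF_b|` with the asymptotic two-sided
  p-value; exact small-sample mode switches on automatically when both
  samples are under 25.
* **Symmetric KL**: both densities re-evaluated by linear interpolation on
  a shared 512-point grid over the union span, floored at 1e-12,
  renormalized; the divergence is the *sum* KL(p‖q) + KL(q‖p)
  (`variant="mean"` halves it). With n = 20000 Gaussian samples the
  estimate lands within 0.15 of the closed form (KDE smoothing biases it
  slightly low, by roughly h² with Silverman's h).
* **Summaries**: median and IQR (Q3 − Q1) with the linear-interpolation
  quantile convention.
* Zero-variance score samples (possible for near-constant instruments in
  a control cohort) raise a degenerate-sample error; the report pipeline
  flags them as point masses, keeps the KS test (which needs no density)
  and reports the KDE-based divergence as NaN.

## Synthetic data generator

`generate_study` emulates a three-cohort observational design: per
participant a reporting-bias vector `b_p ~ N(0, bias_sd²)` per item; per
scheduled timestamp a latent factor vector `z_t ~ N(0, diag(factor_sd²))`
mapped through a sparse loading template W with disjoint column supports;
item values `clip(round(baseline + b_p + W z_t + ε), scale bounds)` with
`ε ~ N(0, noise_sd²)`. Whole records are dropped MCAR with probability
`missing_rate` (item-wise masking is a mode). Factors are i.i.d. across
time to match the exchangeability assumption of the analysis; an optional
stationary AR(1) factor mode supports robustness experiments.

`default_study()` fixes the study conditions: cohorts of 48 (BD-like),
32 (BPD-like) and 51 (control-like) participants over 363 days; daily MZ
and weekly ASRM/QIDS/GAD-7; missing rate 0.2. The MZ template plants the
three 2-item factors anxious+sad, elated+energetic, angry+irritable with
factor sd (1.5, 1.2, 0.9), noise sd 0.8, bias sd 0.7 on the 1–7 scale with
baseline 4: strong enough for reliable recovery at realistic noise, weak
enough that single fits are not trivial. The patient-like cohorts assign
the largest factor sd to anxious+sad (BD second factor positive affect,
BPD second factor irritability) and the control cohort to
elated+energetic, so cohort differences live in component *order*, not
membership. The control cohort's mania-scale (ASRM) factor sds are halved,
emulating the near-degenerate mania variability of healthy controls.
Weekly instruments use narrower-scale templates (factor sd 0.9/0.7/0.5,
noise 0.5, bias 0.4) with cohort-specific supports, so their sparse
structure is intentionally *not* consistent across cohorts.

What the generator does **not** emulate: mood-episode dynamics
(mania/depression cycles), informative missingness, medication effects,
floor/ceiling asymmetries beyond clipping, or item-level ordinal response
processes (a graded-response IRT model would differ). Passing recovery
tests therefore show the estimator chain is correct under the planted
linear-Gaussian-discretized model, not that real questionnaire data has
this structure.

## Pipeline

`run` builds, centers and fits every instrument × cohort slice (dense PCA
baseline, SPCA, first-stage cardinality path), then compares cohorts for
instruments with consistent sparse supports. Everything is deterministic
from `AnalysisConfig.seed`; the config hash and per-slice sample counts go
into the report manifest. `merged_instrument_fit` concatenates the weekly
instruments (ASRM + QIDS domains + GAD-7 = 21 columns) aligned by
participant and ISO week — weekly completion times are not aligned across
instruments, so the calendar week is the natural join key — listwise
deleting weeks where any instrument lacks a complete record.

## Problem sizes

The test suite runs the full default study (131 participants × 363 days,
≈54k records) once for the structural check; the planted-support recovery
experiment uses 100 replicates of a 50-participant × 300-day single-cohort
study; solver-vs-enumeration checks use 100 random covariances with 4–7
items over all cardinalities; divergence calibration uses n = 20000
Gaussian samples and KS calibration 1000 null replicates of n = 500.

## Known limitations

* Cardinality-constrained truncated power iteration is a heuristic for an
  NP-hard problem; global optimality is only *verified* for M ≤ 7 (by
  enumeration in the tests) though the multistart scheme is expected to be
  exact at questionnaire scale generally.
* Adjusted variance is order-dependent; reordering correlated components
  redistributes their increments.
* Symmetric KL on KDE densities inherits smoothing bias (≈ h² shrinkage
  toward zero separation) and depends on the bandwidth rule; values are
  comparable within one configuration, not across bandwidth choices.
* Listwise deletion is only unbiased under MCAR; informative missingness
  in real mood data would bias both loadings and divergences.
* The analysis treats repeated records from one participant as
  exchangeable; strong within-participant autocorrelation inflates the
  effective sample size implied by KS p-values.
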