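# Methods

## The interaction variable

All spatial quantities are computed on 2D cell centroids in micrometres
inside rectangular imaged regions. Distances are centroid-to-centroid
Euclidean; nearest-neighbor queries run on a k-d tree
(`scipy.spatial.cKDTree`), which the test suite holds exactly equal to an
O(n²) brute-force scan on random regions.

For a region with `n_CD8` CD8(+) T cells and `n_TAM` PD-L1(+) TAMs,

```
iv(r) = 100 · #{CD8 cells whose nearest PD-L1(+) TAM is within r} / (n_CD8 + n_TAM)
```

Conventions, each of which was a genuine design choice:

- **Boundary**: "within r" is read inclusively (distance ≤ r); configurable.
- **Phenotype gates**: PD-L1(+) TAM = (CD68 or CD163) and PD-L1; CD8 T cell
  = CD8. The macrophage gate is an OR because pan- (CD68) and M2- (CD163)
  markers are co-stained without an explicit combination rule in typical
  panels; an AND gate is one flag away. Cells satisfying both the TAM and
  CD8 gates are resolved by an explicit precedence list (TAM first) and
  logged, never dropped.
- **Degenerate regions**: `iv = 0` (a defined value) when CD8 cells exist
  but no TAM — no interaction is observable and the denominator is
  positive; `iv` is missing (NaN) only when the region contains neither
  population. Missingness propagates explicitly, never as 0.
- **No edge correction** is applied for cells near region borders. This is
  a known, deliberate bias shared with the standard phenoptr-style
  workflow the package emulates; at 25 µm against ~600 µm fields the
  boundary layer is small.
- **Patient aggregation**: 3–4 biopsy cores per patient are combined by
  pooling numerators and denominators (default), which weights cores by
  cellularity; an unweighted mean of per-core scores is also implemented.
  How cores should be combined is genuinely underdetermined, so both are
  exposed and the choice is a parameter.
- **Radius sensitivity**: `iv` is recomputed at 15/30/50 µm and compared to
  the 25 µm reference by Spearman rho with average ranks and the
  t-approximation p-value; constant columns yield NaN rho, flagged. `iv`
  is monotone nondecreasing in r, with limit `100·n_CD8/(n_CD8+n_TAM)`.

Second-order spatial statistics (Ripley's K and relatives) are out of
scope by design; the analysis is deliberately first-order.

## The synthetic-data generator

The generator realizes *proximity without density change*. In a
`width × height` rectangle (default 600 × 600 µm):

- PD-L1(+) TAM, CD8, and bystander counts are independent Poisson draws at
  intensities `lambda_tam = 2e-4`, `lambda_cd8 = 4e-4`, `lambda_other =
  8e-4` cells/µm² (≈ 70, 140, 290 cells per field — densities in the range
  of immune-infiltrated liver-tumor biopsies). TAMs and bystanders are
  uniform.
- Each CD8 cell is, with probability `attraction_pi ∈ [0, 1]`, an offspring
  of a uniformly chosen TAM parent displaced by an isotropic Gaussian of
  scale `sigma` (default 10 µm, about one cell diameter) — a Thomas-like
  cluster construction; otherwise it is uniform. Offspring falling outside
  the region are resampled (≤ 100 attempts, then clamped to the boundary
  and logged); with zero TAMs drawn, offspring fall back to uniform
  placement (logged). Resampling rather than wrapping keeps the region a
  plain rectangle. Because only *positions* change with `attraction_pi`,
  marginal counts are identical across attraction levels, which is exactly
  the property the normalized score is supposed to isolate.
- Marker flags are consistent with each cell's intended phenotype (TAMs:
  PD-L1 plus CD68 and/or CD163; 30% of bystanders are CD163-only,
  PD-L1-negative macrophages), so generated tables pass the same phenotype
  rule and I/O validation as real exports.
- Functional markers: each CD8 cell gains GZMB (and independently TIM3)
  with probability `expit(intercept + 0.04 · iv)` (intercepts −1.5 / −2.0,
  i.e. ~18% / ~12% base rates rising to ~70% / ~60% at iv 60), emulating
  the coupling of cytotoxic/exhaustion phenotypes to the interaction level.
- Survival: event times are exponential with rate
  `baseline_hazard · exp(beta_iv · iv)` (defaults 0.4/day and −0.15 per iv
  unit), censoring uniform on (0, 1500] days (~4-year accrual). The
  exponential model makes the Cox partial likelihood correctly specified,
  so parameter recovery is a clean end-to-end check. Per-patient ground
  truth is `attraction_pi`; outcomes are generated from the *measured* iv
  so the survival stack can be tested in isolation from spatial sampling
  noise.

What the generator does **not** emulate: fluorescence intensities and
classifier noise in phenotype calls, tissue masks, necrosis/fibrosis
exclusions, irregular core geometry, 3D structure, and informative
censoring. Passing tests therefore demonstrate correctness of the
measurement and inference chain under the stated generative model, not
robustness to segmentation or staining artifacts in real slides.

## Survival analysis

- Median dichotomization labels `high` as value ≥ median (midpoint
  convention for even counts), so 23 distinct scores split 11 low / 12
  high; all-equal inputs put everyone in `high` with a warning.
- Kaplan–Meier and the two-group log-rank test are delegated to lifelines
  (product-limit estimator; hypergeometric-variance statistic against a
  1-df chi-square). A subject censored at an event time remains at risk for
  that event.
- Cox proportional-hazards fitting is implemented in-package as a
  Newton–Raphson maximizer of the partial likelihood with Efron (default)
  and Breslow tie handling behind one code path — on tie-free data the two
  conventions coincide to machine precision by construction. Covariates
  are centered for conditioning (coefficients unaffected). Inference is
  Wald: 95% CI = `exp(coef ± 1.96·SE)`, p from the normal approximation —
  the convention of clinical survival software; likelihood-ratio intervals
  are not provided. Monotone likelihoods (a covariate perfectly ordering
  events) are detected by coefficient divergence (|β| > 20) or a
  non-vanishing gradient at termination and raised as errors naming the
  covariate. lifelines' `CoxPHFitter` and a brute-force grid maximizer
  serve as independent cross-checks in the tests, never as the
  implementation.
- Screening fits each candidate alone, passes those with Wald p < 0.05
  into one multivariate model, records per-candidate failures without
  aborting, and returns an explicit empty-selection report when nothing
  passes.

## Internal validation

- The ROC curve and AUC come from scikit-learn (trapezoid AUC = Mann–
  Whitney concordance with half-credit ties). Youden's J = sensitivity +
  specificity − 1 is maximized over observed thresholds; ties resolve to
  the lowest threshold (most sensitive operating point).
- The 1-year progression label marks event-free survival past 365 days as
  positive; patients censored before the horizon have unknown status and
  are excluded (count logged). This is the least-assumption handling of an
  underdetermined labeling problem.
- Optimism correction follows Harrell's procedure with the patient as the
  resampling unit: refit the model on each bootstrap resample, evaluate the
  metric on the resample and on the original sample, average the
  difference, and subtract it from the apparent metric. Single-class (for
  AUC) or zero-event (for the C-index) resamples are redrawn, counted, and
  capped at 50 redraws per iteration. Substituting the original sample for
  every resample yields optimism exactly 0. With a fixed seed every output
  is bit-reproducible.
- **A degeneracy worth knowing about**: when the logistic (or Cox) model
  contains a single covariate, the fitted model's predictions are a
  monotone transform of that covariate (up to sign), so rank metrics —
  AUC, C-index — cannot be overfit by refitting: the estimated optimism is
  bootstrap noise centered at ~0 (measured within ±1e-3 at n = 200,
  1000 iterations) and its sign is uninformative. The
  single-interaction-variable validation mirrors the primary analysis and
  honestly reports that near-zero optimism; demonstrations of the
  overfitting *direction* (corrected < apparent) use models with genuine
  capacity — the marker plus noise covariates — where optimism is
  decisively positive. `bootstrap_optimism_auc` accepts either a single
  marker or a feature matrix for this reason.

## Clinical scores

ALBI = 0.66·log10(bilirubin µmol/L) − 0.085·albumin (g/L), with unit
conversion from conventional units (bilirubin ×17.104 from mg/dL, the molar
factor; albumin ×10 from g/dL) applied before the formula. Modified ALBI
grades use boundaries closed on the lower-grade side: 1 (≤ −2.60),
2a (≤ −2.270), 2b (≤ −1.39), 3 (above). Child–Pugh class is consumed as a
precomputed column; its ascites/encephalopathy inputs are outside the data
model.

## Problem sizes and numerical choices

Test and acceptance runs use 40–200 regions per condition, cohorts of
120–300 patients, 100–200 Monte Carlo replicates, and 200–1000 bootstrap
iterations — sizes at which every Monte Carlo assertion has comfortable
margin while the whole suite stays interactive. Fixed seeds make every
stochastic check reproducible. Floating-point conventions: spatial counts
are compared exactly against brute force; rigid-motion invariance is
asserted at 1e-9 on distances; closed-form fixtures (product-limit,
log-rank, AUC pair-counting, ALBI) at 1e-12; cell-table round-trips are
bit-exact because coordinates are written at full precision and parsed with
a correctly rounded parser.

## Known limitations

No edge correction (above); no tissue masking, so the denominator region is
the full rectangle; the exponential outcome model has proportional hazards
by construction and cannot probe misspecification; overall-survival times
are drawn independently of progression times (no semi-competing-risk
structure); post-hoc power estimation is deliberately not implemented.
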