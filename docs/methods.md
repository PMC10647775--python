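# Methods

## Problem and data model

The package addresses individual (not population-average) craniofacial
growth prediction: given one child's serial lateral cephalometric records
at ages 6 through 12, predict the same quantities at age 13. A record at
one age is the 2-D position of 26 skeletal landmarks digitized from one
film, from which 13 linear (inter-landmark distances, mm) and 17 angular
(inter-line angles, degrees) parameters are derived — 56 measurement items
per subject-age.

All computation happens in a normalized anatomical frame: per film, the
sella is translated to the origin, the frame is rotated so the nasion lies
on the **positive x-axis**, and pixel coordinates are divided by a single
dataset-wide pixels-per-mm constant. Placing the nasion on +x (rather than
merely "parallel to the x-axis") fixes a unique frame; the choice of side
is conventional. The frame is right-handed with superior = +y; inputs are
assumed mirror-consistent — scanned films share chirality, and no
reflection detection is attempted. Each age is normalized independently
from its own sella→nasion vector, which makes every derived measurement
exactly invariant to per-film rotation, translation and (jointly with the
mm conversion) scale; the geometry invariance suite asserts this to 1e-9.

Missing interior years (ages 7–11 only; every subject is anchored at 6, 12
and 13) are filled per landmark per coordinate by linear interpolation in
age between the nearest observed years. Linearity is the minimal
assumption at annual sampling. The pipeline interpolates **after**
normalization by default (interpolating raw pixel coordinates would mix
per-film acquisition transforms into the interpolant); a
`before_normalize` option exists for comparison.

## Angle conventions

An angular parameter is the unsigned angle in [0, 180]° between the two
directed segments listed in its definition, via the arccosine of the
normalized dot product. No clinical sign convention is applied; in
particular ANB computed this way equals |SNA − SNB| only when the A and B
points lie on the same side of the S–N line, and no negative ANB is ever
produced. Convexity and the A–B plane angle are reported as the raw
inter-line angle; a `clinical_convexity` switch yields the familiar
180°-complement reading. The "Occlusal pl to SN" angle uses the segment
from the upper-incisor tip to the occlusal-plane landmark, exactly as the
parameter's landmark list reads.

## Predictive models

Features are all measurement items over the input age window (default
6–12, 7 ages); targets are the items at age 13. A 2-D landmark enters a
regression through its two coordinates, so the "56 items per age" and the
"82 columns per age" (x and y counted separately) readings produce the
same design matrix; the `layout` flag changes item accounting only.

- **Stepwise MRA.** Forward-backward greedy selection scored by adjusted
  R²: from the empty model, repeatedly add the best single feature, then
  remove any feature whose removal improves the score, until no single
  move improves. Final coefficients are plain OLS on the selected set.
  Ties break to the earliest feature in schema order; steps that would
  leave fewer than two residual degrees of freedom are skipped (the
  selection can otherwise outrun n in the p ≫ n regime); a constant
  target yields the intercept-only model. Tests verify each accepted step
  against an exhaustive single-move scan.
- **LASSO.** Coordinate descent (scikit-learn) under the objective
  (1/(2n))·RSS + λ‖A‖₁ with unpenalized intercept on z-scored features;
  written without the 1/(2n) factor the penalty is the same up to a
  rescaling of λ, and since λ is chosen by inner cross-validation over a
  data-driven log grid (from λ_max, the smallest all-zero penalty, down
  to eps·λ_max), the convention does not affect the selected model.
  Coefficients are reported on the original scale; the selected-feature
  set is read off the standardized coefficients at 1e-10. KKT subgradient
  conditions, the OLS limit and the full-shrinkage limit are asserted in
  tests.
- **RBFN.** Gaussian bases centred on fuzzy c-means centroids (fuzzifier
  m=2, tolerance 1e-5, ≤300 iterations; hand-implemented Bezdek updates)
  over z-scored features, one shared width σ, and output weights trained
  by full-batch momentum SGD (lr 1e-4, momentum 0.9, 2000 epochs
  default). The model is a pure linear combination of bases (no output
  bias). (M, σ) are selected by seeded random search — M ∈ [2, 20] and
  σ ∈ [0.1, 10] log-uniform — scored on a held-out 20% of the training
  subjects and refit on all training rows; random search keeps the
  selection fully seeded and reproducible at these budget sizes.
- **MLP.** Two 64-unit ReLU hidden layers and a **linear** output layer,
  full-batch momentum SGD (lr 0.01, momentum 0.9) on MSE over z-scored
  features and targets, Glorot-uniform initialization from the seed. A
  ReLU output would confine standardized targets to the nonnegative
  half-line, so the output activation is deliberately linear.
- **GBDT.** LightGBM regression per target, single-threaded and seeded
  (`deterministic=true`); learning rate, leaf count, depth and minimum
  leaf size are chosen by seeded random search with early stopping
  against a 20% validation split, then refit at the early-stopped round
  count.

MRA, LASSO and GBDT fit one model per scalar target; RBFN and MLP are
multi-output and fit all requested targets jointly. Every fitted model
predicts in natural units (standardization applied and inverted
internally), serializes to JSON text, and reproduces its predictions
bit-identically after a save/load round trip.

## Evaluation design

Subjects are partitioned into k = 10 near-equal random folds (59 subjects
give nine folds of 6 and one of 5). All tuning — λ grids, (M, σ) search,
GBDT tuning — is nested inside each fold's training subjects; held-out
age-13 values never reach any fitting code (asserted via an
instrumentation hook). Per-target RMSE is computed per fold and averaged
across folds (default; a pooled-residual mode is a flag). A landmark
target's squared error is the squared Euclidean distance between
predicted and actual 2-D points, giving one mm-valued error per landmark;
per-axis errors are available as optional columns. The sella is excluded
from landmark reporting (it is the origin by construction), leaving 25
landmark rows + 13 linear + 17 angular = 55 reported targets. The N–S
distance can be dropped from the linear family (`include_ns=False`,
12-row mode).

Accuracy is 100 × (1 − RMSE / mean actual value), with the family
denominator taken as the grand mean of actual age-13 values over all
subjects and member targets; it is emitted for the linear and angular
families only, because signed normalized coordinates have a non-positive
mean and the ratio is undefined there.

The age-window experiment repeats the cross-validation with the feature
window restricted to {6}, {6–7}, …, {6–12} and reports the overall average
landmark error per window; on cohorts with subject-specific growth rates
and placement noise the error decreases as the window widens, because
each added year sharpens the estimate of the subject's growth slope.

## Synthetic cohort generator

The generator emulates the structure of a longitudinal growth study with
59 untreated children filmed annually at ages 6–13:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 59 | cohort size |
| `landmark_template` | built-in | 26-point facial template (mm); the intercept of the linear growth model, sella at origin, nasion on +x |
| `growth_vectors` | built-in | per-landmark mean annual displacement (mm/yr), the familiar down-and-forward pattern |
| `subject_sd` | 0.1 | SD of the per-subject growth-rate multiplier (random slopes, mean 1) |
| `noise_sd` | 0.5 mm | landmark placement noise, the dominant error of hand tracing |
| `acquisition` | ±5°, ±200 px, 10 px/mm | per-film rigid transform ranges and the dataset-wide pixel scale |
| `missing_rate` | 4/(59·5) | per-cell probability an interior age (7–11) is unfilmed, matching about four missing films per cohort |
| `quadratic` | 0 | optional curvature term for non-linear trajectories |

True positions follow template + age·growth·multiplier (+ optional
quadratic term); noise is added in mm, then the film transform is
applied. One scalar multiplier per subject scales all growth vectors —
the simplest random-slope structure consistent with a pooled-sex cohort
(sex is not modelled, matching a pooled analysis). Four independent,
documented RNG streams (multipliers / noise / acquisition / missingness)
make every draw independently replayable.

`proportional_growth(rate)` supplies growth vectors proportional to the
template positions at a shared relative rate: the whole face then scales
uniformly with age, coordinates and distances become exactly affine
functions of any single earlier age's value and every angle is constant.
This idealized fully-linear regime is what the exact-recoverability test
uses — cross-validated LASSO must recover all 55 targets to below 1e-6 of
their scale there. The default per-landmark vectors are the realistic
setting, where angles change non-linearly over age.

What the generator does **not** emulate: sexual dimorphism and pubertal
growth spurts (trajectories are linear or mildly quadratic in age),
correlated regional deformation (noise is iid per landmark), landmark
identification ambiguity on real films, and secular/ethnic variation in
facial form. Passing tests therefore demonstrate the correctness and
statistical behavior of the pipeline under the stated model, not clinical
accuracy on radiographs.

## Numerical choices

- λ grids: 16 points (default) log-spaced over [eps·λ_max, λ_max];
  evaluation runs use 8 points with eps = 1e-2 and coordinate-descent
  tolerance 1e-6 (errors are noise-dominated there); exactness tests use
  eps = 1e-8 with tolerance 1e-12.
- Constant-target guard: a target whose SD is below 1e-12 of its value
  scale is fit as intercept-only and flagged in the report.
- Z-scoring uses training-fold statistics only; constant columns get SD 1
  so they standardize to zero.
- Fuzzy c-means floors point–centroid distances at 1e-12; non-convergence
  within 300 iterations returns the best iterate with a warning.
- Ties everywhere (stepwise candidates, search trials) break to the first
  candidate in schema/trial order, making every fit deterministic.
- Angles clip the normalized dot product to [−1, 1] before arccos.

## Problem sizes used by the shipped runs

The default test suite and the acceptance script are sized for a single
CPU: the exact-recoverability check runs the full 59-subject, 10-fold
LASSO evaluation; the age-window trend check uses 30-subject cohorts, a
10-landmark subset, 3 folds and 10 seeds; the acceptance script runs the
59-subject LASSO and baseline evaluations at 10 folds and the age-window
comparison at 3 folds with windows {6}, {6–9}, {6–12}. These sizes are
stated here so results can be reproduced exactly; widening them is a
matter of passing larger values.

## Known limitations

- 2-D cephalometry only; no 3-D (CBCT) support.
- No sex-specific or maturity-staged modelling; no covariates beyond the
  landmark record.
- The unsigned-angle convention differs from clinical sign conventions
  for ANB and convexity (documented above).
- LASSO λ selection inside small folds is variance-prone; with ~53
  training subjects and thousands of candidate features the selected
  support should be read as predictive, not anatomically causal.
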