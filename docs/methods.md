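# Methods

## Scope and model

`hsm` implements a presence-background habitat suitability workflow of the
kind used to map forest species (the motivating case: tree-roosting bats)
from co-registered environmental rasters, with an emphasis on comparing two
variable sets that describe the same landscape at different levels of
detail — a *targeted* stack of fine structure/composition indices versus a
*generalized* stack of aggregated products (merged land-cover classes,
block-averaged structure).

The model is the maximum-entropy (Maxent) presence-background model in its
penalized-GLM form. Habitat use is a Gibbs density over the landscape,

    q_beta(x) = exp(f(x)' beta) / Z(beta),

where `f` is the feature expansion of the environmental variables and `Z`
normalizes over the background sample. Fitting minimizes

    -(1/m) sum_{presences} f(x_i)' beta + log Z(beta)
        + sum_j lambda_j |beta_j|,

a convex objective solved by FISTA (accelerated proximal gradient with
backtracking line search and adaptive restart; soft-thresholding produces
exact zeros). The per-feature penalties follow the reference Maxent
defaults: `lambda_j = RM * c_class(m) * sd_j / sqrt(m)`, with `m` the
presence count, `sd_j` the feature's standard deviation over the presence
sample, and `c_class` interpolated from the published per-class tables
(linear/quadratic/product: 1.0 at m<=10 down to 0.05 at m>=100; threshold:
2.0 to 1.0; categorical: 0.65 to 0.25; hinge: 0.5, with a floor of
`0.5*RM/sqrt(m)`). `RM` is the user-facing regularization multiplier.

Feature classes: linear, quadratic, and product act on min-max scaled
values; hinge (forward and reverse) and threshold features use knots at
uniform quantiles of the training background, 50 per variable by default.
Scaling ranges span all training rows — presences included — so clamping
(applied at prediction) never truncates a training presence. Categorical
variables expand to one indicator per observed class and take the
categorical penalty, never hinge or product forms.

Outputs: `raw` is the normalized density (sums to one over the training
background); `cloglog = 1 - exp(-e^H * raw)`, with `H` the entropy of the
fitted density over the background, maps it to a [0, 1] suitability index.
The two are related by a strictly monotone transform, so rank-based
diagnostics are identical between them. Maps default to cloglog; a switch
exposes raw output.

## Selection pipeline

Model configuration is chosen by spatial cross-validation in a fixed,
non-backtracking order:

1. **Forward variable selection** — all C(V,2) variable pairs are scored;
   the best pair seeds the model; single variables are added greedily while
   the mean held-out score improves. During this stage the basis is fixed
   at {linear, quadratic, hinge} with RM = 1, so variable choice is not
   confounded with the later stages.
2. **Forward feature-class selection** — starting from {linear}, greedily
   add quadratic / product / hinge / threshold.
3. **Regularization-multiplier tuning** — grid 0.5 to 7.0 in steps of 0.5
   (14 values); ties go to the larger (more parsimonious) multiplier.

The selection score is the mean held-out AUC (ROC) across spatial folds:
for each fold, fit on the others and score held-out presences against
held-out background. AUC is computed on the linear predictor (rank
equivalent to cloglog). A greedy step is accepted only if it improves the
score by more than `min_improvement` (default 5e-4): improvements below
the solver tolerance's noise floor — for example from adding an exact
duplicate of a selected variable, where the optimum is non-unique — must
not drive selection.

Spatial folds are built by k-means on projected point coordinates (labels
renumbered west to east for reproducibility), replacing the manual cluster
delineation a field study would draw. Background points are sampled
uniformly over valid cells study-wide and inherit the fold of the nearest
occurrence-cluster centroid, since fold-aware scoring needs held-out
background and no convention is established for it.

## Nested evaluation (ffme)

Workflow performance is estimated by forward fold metric estimation: with
k = 7 folds, every unordered pair of test folds is held out in turn
(C(7,2) = 21 splits; the package supports any k >= 3 and test-set size).
Within each split the *entire* selection pipeline reruns on the five
training folds only — true nesting, so no test datum influences any
selection decision — a final model is fitted on all training-fold rows,
and ten metrics are computed on held-out presences against an equal-size
seeded background sample: AUC-ROC, TSS, Cohen's kappa, sensitivity,
specificity, PCC (all five confusion metrics at the TSS-maximizing
threshold), the continuous Boyce index (101 windows of width 0.1 of the
prediction range), the area under the precision-recall-gain curve, Pearson
correlation with the 0/1 labels, and mean absolute error. Because
"absences" are background points, all label-based metrics are
presence-only variants. Split metrics are aggregated by unweighted mean;
two approaches are compared metric-by-metric (MAE won by the smaller
value, all others by the larger).

Kappa uses the standard chance-agreement term from the cross-products of
observed and predicted marginals, and shares the max-TSS threshold with
the other confusion metrics so the five are computed from one contingency
table.

Final maps are fitted on all folds with settings tuned by k-fold spatial
CV, thresholded at the max-TSS threshold of the model's own training
evaluation; map pairs are compared by Pearson r and RMSE over all valid
cells, and by suitable area (1-cells x cell area, km^2), with the area
difference reported unsigned alongside the signed value.

## Synthetic landscapes

Because real roost data are confidential, the pipeline ships a generator
whose defaults define the study conditions used in tests:

- **Fields.** Zero-mean, unit-variance Gaussian fields with exponential
  covariance `exp(-h/range)` (default range 300 m on 50 m cells),
  simulated exactly by circulant embedding; `range = 0` gives i.i.d.
  noise. The landscape mask is a thresholded smooth field (85% valid).
- **Fine stack.** The first `n_true = 3` continuous variables are
  independent structural axes; the truth is logistic in exactly these,
  with coefficients ±1.5 (alternating sign) and intercept −1 (mean
  suitability ≈ 0.35). The remaining indices load 0.4–0.6 on shared
  latent fields, giving the correlated index families real variable sets
  have. A six-class tree-species-like layer (argmax of six latent fields)
  completes the stack.
- **Coarse stack.** The class layer merged six-to-three (the merge table
  is recorded), plus block means (8 x 8 cells = 400 m) of the first fine
  variables with added Gaussian measurement error at 0.5 of the signal's
  standard deviation — emulating how generalized products (global canopy
  height, generic land cover) both smooth away and corrupt stand-scale
  structure. The fine-to-coarse lineage is recorded in `detail_map`.
  An oracle fractional-logit fit of the truth achieves strictly lower
  deviance on the fine stack than on the coarse stack; this information
  ordering is what the end-to-end comparison is expected to recover.
- **Presences.** Cells drawn with probability proportional to suitability;
  with `clustering > 1` the weight is multiplied by Gaussian bumps around
  suitability-weighted centers (sd 8% of the grid side), yielding the
  spatially aggregated point patterns that make spatial folds meaningful.
  Positions are jittered uniformly within cells.

What the generator does *not* emulate: sensor physics, anisotropy,
non-stationary covariance, observation bias correlated with predictors,
and temporal structure. Passing tests therefore show the pipeline's
statistical machinery is sound under known conditions, not that any
particular real-world variable set is superior.

## Problem sizes in tests

The reference design (7 folds, 50,000 background points, RM grid to 7.0)
is the package default. The test and acceptance runs use reduced problem
sizes chosen as the smallest at which the studied effects are stable:
parameter recovery on a 128 x 128 grid (1000 presences / 10,000
background for the map-recovery fit; 600 / 4000 per forward-selection
replicate, 20 replicates); the two-approach comparison on a 96 x 96 grid
(250 presences, 5 folds, C(5,2) = 10 splits per approach, 10 replicates);
selection unit tests with 4 hinge knots and solver tolerance 1e-5.

## Numerical choices

- FISTA stops when the relative objective change drops below `tol`
  (1e-7 final fits, 1e-5 inside selection loops); hitting `max_iter`
  raises a `ConvergenceError` carrying the objective trace (selection
  loops downgrade this to a warning and keep the best iterate).
- RM-grid refits warm-start from the previous grid point's coefficients.
- The raw output's normalizer and the entropy `H` are frozen from the
  training background at fit time; predictions on new data reuse them.
- Thinning uses randomized greedy elimination (drop the point with most
  neighbors closer than the minimum distance, ties uniform) over 10
  trials, keeping the largest survivor set; points are canonically sorted
  first so the result is independent of input order. On instances small
  enough for exhaustive search the greedy survivor count matches the
  maximum independent set.
- The correlation prefilter removes, from the worst offending pair, the
  variable with the larger mean absolute correlation against the
  remaining set (the caret `findCorrelation` rule); |r| is used, so
  strong negative correlation is also excluded; zero-variance variables
  are dropped first with a warning.
- Half-open raster cells: a point on a shared vertical edge belongs to
  the cell on its right, on a shared horizontal edge to the cell below;
  the grid origin is the upper-left corner. The package never
  reprojects — stacks and occurrences must share a projected, meter-based
  CRS, and geometry mismatches raise rather than resample.

## Known limitations

- The Boyce index's null distribution is wide under the ecospat-like
  defaults (101 heavily overlapping windows): single-run values scatter
  roughly ±0.35 around zero for uninformative predictions. Means across
  replicates are well behaved; single-split CBI values should be read
  with that in mind.
- Greedy forward selection under strong predictor collinearity can
  substitute a correlated proxy for a true driver; the recovery tests
  quantify this at the shipped conditions (about 95% of replicates
  recover all three drivers).
- k-means folds approximate, but do not reproduce, hand-drawn geographic
  clusters; fold sizes are not balanced.
- GeoTIFF support covers single-band, square-cell rasters with the
  standard georeferencing tags; no reprojection, mosaicking, or cloud
  formats.
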