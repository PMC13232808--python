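# Methods

This note documents the models, defaults and numerical choices behind
`nichekit`, and what the synthetic validation does and does not demonstrate.

## Modelling space

All analysis happens on a single raster grid: row 0 is the northernmost row,
the grid origin is the outer top-left corner of cell (0, 0), cell centers
carry coordinates, and extents are half-open. Layers are stacked under one
shared validity mask (the intersection of per-layer valid regions); masked-in
cells are guaranteed finite everywhere downstream. GeoTIFF georeferencing
(pixel scale, tiepoint, EPSG geokey, GDAL nodata) is read and written
directly on top of `tifffile`; reprojection between CRSs is out of scope, so
all inputs must share one CRS. Resampling supports integer-factor mean
aggregation (valid cells only; an all-invalid window becomes masked) and
integer-factor nearest-neighbour refinement. The conventional target
resolution for projected stacks is 250 m, carried as a default, not a
requirement.

## Collinearity screening

Pairs with |Pearson r| ≥ 0.7 (computed over masked-in cells) are visited in
decreasing |r|; within a pair the variable with the higher mean absolute
correlation to all other variables is dropped, with ties broken against the
variable later in the priority order (alphabetical by default). This greedy
rule is deterministic, idempotent (re-screening the retained set drops
nothing), and guarantees the retained set contains no violating pair. Which
member of a correlated pair survives is a genuine free choice in this family
of workflows; the mean-|r| rule keeps the variable that carries the most
independent information. Zero-variance layers are treated as uncorrelated.

## Occurrences and pseudo-absences

Formatting order is: snap to grid and deduplicate to one record per cell
(keeping the first in input order, moving points to cell centers), then cap
by uniform subsampling (default 500). Dedup-first maximizes spatial coverage
of the retained sample. Pseudo-absences (default 1,000) are drawn uniformly
without replacement from the masked-in study area, excluding presence cells
by default — sampling a labelled presence cell as an absence would put
contradictory labels on identical predictor rows; a flag restores the
unconstrained behaviour. Class balancing is on by default: presence weights
are scaled so total presence weight equals total absence weight (effective
prevalence 0.5), recording the choice explicitly rather than letting
prevalence vary silently with sample size.

## Member models

The six member tags are an interface; each is backed by a standard learner of
the named family:

| Tag  | Family                      | Backing                                          |
|------|-----------------------------|--------------------------------------------------|
| GBM  | boosted trees               | sklearn `GradientBoostingClassifier` (100×d3)    |
| RF   | random forest               | sklearn `RandomForestClassifier` (200 trees)     |
| ANN  | single-hidden-layer network | sklearn `MLPClassifier` (8 units)                |
| MARS | adaptive piecewise-linear splines | in-package hinge-pair basis (quartile knots) + L2 logistic |
| GAM  | smooth additive model       | cubic B-spline basis (5 knots) + L2 logistic     |
| CTA  | classification tree         | sklearn `DecisionTreeClassifier` (depth ≤ 8)     |

All members emit probabilities in [0, 1]. Sample weights are honoured via
`sample_weight` where supported; the MLP has no weight interface, so rows are
replicated in proportion to their weight (rounded, capped at 50×) — exact for
the integer ratios produced by class balancing. Hyperparameters are fixed,
moderate defaults; tuning is a non-goal.

## Evaluation, gating, ensembles

Each member is evaluated by stratified random 70/30 calibration/evaluation
splits over 3 replicates. TSS and Kappa are computed at the TSS-maximizing
threshold of the held-out scores (candidates = unique scores ∪ {0, 1};
smallest maximizer wins, a deterministic tie-break); AUC is the rank
(Mann–Whitney) statistic with ties counted ½. Members with mean AUC ≥ 0.7
(inclusive) enter the ensemble; gating on the mean rather than per replicate
is an explicit choice. EMwmean weights are proportional to member mean AUC —
the simplest rule monotone in skill. EMcv is sd/mean of member predictions
(0 where the mean is 0; sample sd, ddof 1), and EMci is mean ± z₍₁₋α/₂₎·sd
with α = 0.05, clipped to [0, 1] — a named summary whose exact form is an
implementation decision recorded here.

The binarization threshold is the TSS-max cutoff of the *pooled held-out
EMwmean scores*: all members share the same per-replicate splits (derived
from the seed alone), so the weighted mean of member held-out scores is well
defined per replicate, and pooling across the three replicates uses every
held-out point once.

Permutation importance of a predictor is the mean over permutations (default
3) of 1 − Pearson correlation between EMwmean predictions before and after
shuffling that predictor's column, clipped to [0, 1] — the prediction-
correlation convention of ensemble-SDM frameworks, not a metric drop.

All stochastic steps take explicit seeds; a master seed fans out through a
hash-based `derive_seed(master, *tags)` so any stage can be re-run in
isolation with identical results.

## Change statistics

* **Areas** are per-cell km²: `(cell/1000)²` for projected grids (cell size
  in metres); `(cell·111.32)²·cos(latitude)` per row for geographic grids.
* **Range change**: RCI = (S_col − S_ext)/S_present × 100 over areas, with an
  explicit error (not NaN) when the baseline range is empty. −100 means
  complete loss; 0 means gains exactly offset losses.
* **Schoener's D**: each map normalized to sum 1 over masked-in cells,
  D = 1 − ½Σ|p − q|. Default mode is `binary` (thresholded range maps as
  input); `continuous` mode is provided and is invariant to positive
  rescaling. Relative overlap change is 100·(D_future − D_base)/D_base,
  reported to one decimal.
* **Centroids** use component-wise medians of suitable-cell centers (and
  their elevations) — robust to outlying cells; an even count takes the
  midpoint of the central pair. The genus-level centroid is offered both as
  the centroid of the union of suitable cells and as the mean of species
  centroids, since either definition is defensible.
* **Period averaging** across multiple future windows defaults to the mean of
  continuous suitability maps before thresholding, with a
  majority-of-binaries alternative.
* **Richness** is the per-cell sum of species binaries, normalized by species
  count; ΔSR is future − baseline.

## Synthetic validation

`generate_landscape` produces independent Gaussian random fields (white noise
convolved with an isotropic Gaussian kernel, sigma in cells), standardized
exactly to mean 0/sd 1, optionally with a deterministic north–south linear
trend added to named layers before standardization (a temperature-like
field). Virtual species are either a product of per-variable Gaussian bells
rescaled to max 1, or a logistic-additive response whose intercept is solved
(Brent's method) to hit a target prevalence. Occurrences are cells drawn
without replacement with probability proportional to true suitability —
mirroring the one-record-per-cell formatting downstream — with an optional
uniform misdetection fraction. Scenarios are additive shifts of chosen
layers, so the true post-change suitability, and hence the true RCI and
centroid movement, are computable exactly.

The standard validation scene (`benchmark_scene`) is a 100×100 landscape of
five layers (autocorrelation range 5 cells) with one narrow-niche specialist:
Gaussian response on the first layer, optimum 0.5, breadth 0.15 in
standardized units, sampled with 200 presences against 1,000 pseudo-absences.
The breadth was chosen so that the species is genuinely identifiable: the
true-suitability score itself separates suitability-weighted presences from
uniform background at AUC ≈ 0.9, leaving a competent ensemble room to clear
0.85 held out. With a gradient strength of 1.5 on the driver, a positive
(warming) shift provably moves the suitable band poleward, which the
centroid tests assert. The truth-recovery studies use the three fast tree
members (RF, GBM, CTA) to keep a full 10-seed study inside a short run; the
six-member set is exercised on smaller separable fixtures.

What the synthetic tests do **not** show: real occurrence data carry spatial
sampling bias, positional error and non-equilibrium distributions; real
predictors are strongly cross-correlated with heavy-tailed distributions; and
real climate change is not an additive shift of standardized layers. Passing
the truth-recovery suite demonstrates the estimator chain is implemented
correctly and is statistically consistent under its own assumptions — not
that any field application will achieve comparable accuracy.

## Numerical details and edge cases

* Metric preconditions are enforced with typed errors: both classes present
  (AUC, thresholding), non-empty marginals (TSS/Kappa), p_e < 1 (Kappa),
  non-empty baseline range (RCI), positive map totals (D), non-empty suitable
  set (centroids).
* A member that fails to fit becomes a flagged failure record and the
  pipeline continues with the remaining members; an empty gated set is an
  explicit no-ensemble error.
* Threshold scanning is vectorized over all candidates; equality at the
  maximum is resolved to the smallest candidate within 1e-12.
* The fixture writer (`make_fixture`) emulates a strongly imbalanced
  four-species survey (1400/206/418/37 records on the default 100×100 grid —
  one widespread, two intermediate, one rare taxon) across three labelled
  scenario stacks of increasing shift magnitude, with species niche breadths
  narrow enough (0.30–0.15) that fitted members clear the AUC gate.
* Problem sizes in the test suite (100×100 grids, ≤ 20 seeded replicates)
  were chosen to keep the full suite within a few minutes on one CPU while
  leaving the statistical assertions well-powered.
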