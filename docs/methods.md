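# Methods

## Vulnerability, not risk

Throughout the package, *vulnerability* is the expected relative biomass
loss conditional on a disturbance occurring (`BL_rel` when observed,
`PBL_rel` when model-predicted, both fractions of pre-event biomass). No
occurrence probability and no exposure enter any quantity; the overall
vulnerability index is therefore a conditional-loss union, not a risk
index.

## Biomass reconstruction

The reconstruction assumes biomass change is fully conditioned by
tree-cover change. Cover lost after the 2010 reference year subtracts
biomass at the local loss density ρ_loss; cover lost before it is added
back going backwards in time; gain pixels ramp linearly over 2000–2012
toward the maximum cover observed within a 2.5 km circular window (the
"maximum potential tree cover" of the local environment), so their 2010
cover is exactly 10/12 of the 2012 value. We use the exact 10/12 ratio
rather than its two-decimal rounding: the factor is derived, not
measured. Densities are per-pixel ratios `B_2010 / TC_2010` on the
respective masks, spatialized as medians over coarse blocks (default 8×8
pixels, standing in for a 0.1° aggregation of 100 m pixels) and
nearest-filled where a block has no defined pixel. Domains with no
loss (or gain) pixels at all need no density and get a zero field; loss
pixels whose ratio is nowhere estimable raise an error instead of
guessing.

Two deliberate literalisms: the sign switch of the loss term flips at
2009 (`α = +1` iff `t < 2009`), reproducing the stated rule even though
the reference year is 2010 — the boundary is configurable
(`alpha_boundary_year`); and the gain denominator decade (10) coexists
with the 12-year gain ramp, as printed. The gain cover in the annual
equation is the *static* 2010 gain grid with all time dependence in
`(2010 − t)/10`; a per-year rescaling reading would double-scale time
and is not used. Negative reconstructed biomass is clipped to zero.

## Response variable and lags

`BL_rel` compares the pre-event maximum with the post-event minimum of
the patch-mean biomass series. Backward/forward lags are (1, 1) for
fires and windthrows (abrupt loss) and (2, 5) for insect outbreaks
(slow, progressive decline). Only records with `BL_rel > 5%` (strict)
are retained. Dynamic predictors are sampled at `t − 1`; the pre-event
year is not pinned by the source description, so the lag is a
configurable default of one year. Footprint membership uses the
half-open pixel-center convention.

## Model training

*Resampling.* Records are standardized, projected on the first three
principal components (correlation-matrix PCA — predictors have
heterogeneous units), and binned on a 20×20×20 equal-width lattice
spanning the pooled range; the 60/40 split is per-year, seeded, without
replacement (years with fewer than two records go wholly to training).
Bin aggregates are means weighted by record area; bins with fewer than
three records are dropped; PFT cover fractions are aggregated the same
way and renormalized per bin. The lattice tempers the strong spatial
clustering of disturbance records. It presumes record counts well above
the occupied-lattice size (tens of thousands in the source datasets;
about five thousand in our default study condition). At the few hundred
records a desk-scale grid yields, almost every occupied cell is a
singleton, so the pipeline driver falls back to training on the
year-stratified record split directly whenever fewer than 20 train or
10 test bins survive; library users calling `pc_bin_split` directly get
the unmodified procedure.

*Feature selection.* An approximate model on the full predictor set
supplies importances; of every pair with |Spearman ρ| > 0.8 the less
important member is pruned (ties drop the lexicographically later name);
backward elimination then removes the least important predictor per step
and the subset maximizing test R² wins (ties prefer the smaller set).
The 0.8 threshold is applied to |ρ|.

*Fitting.* 500 regression trees; tree depth (3–20) and per-split feature
count (1–|Q|) come from a seeded 32-draw randomized search scored on
out-of-bag R² — the search plays the role of a Bayesian optimizer
without the dependency, and fixed hyperparameters can be passed to skip
it. PFT-specific models keep only bins with that PFT's fraction above
5% (at least ten required) and multiply sample weights by the fraction.
Variable importance is permutation importance measured on the held-out
binned test set (unbiased, model-agnostic); impurity importance is
available behind a flag. Predictions are clipped to [0, 1].

*Validation.* R² = 1 − SSE/SST (missing when SST = 0), RMSE, NRMSE
(RMSE over the observed range), PBIAS = 100·Σ(pred − obs)/Σobs, and
per-bin relative errors, all on the held-out binned set.

## Interpretation

Partial dependence uses 50 equally spaced points spanning the observed
range and is zero-centred for display and for all derived statistics.
Friedman's H for a pair is computed at the data points (a seeded
subsample, default 500 rows) with coordinates snapped to the 50-point
grids: `H² = Σ(PD_ij − PD_i − PD_j)² / Σ PD_ij²` on centred partial
dependences, reported as H ∈ [0, 1]; a flat two-way surface reports 0
with a warning. ΔP compares the peak of the centred two-way surface
with the peak of the sum of centred one-way curves, in percent of the
latter; centred (rather than raw) one-way references are a deliberate
choice. Category-level interaction strength is the arithmetic mean of
pairwise H over all pairs spanning the two categories. Local
sensitivity is the OLS slope of a grid cell's ICE curve over the full
training range of the predictor (an option restricts the fit window);
`Z_marg` shares the total absolute slope among the forest, climate and
landscape categories and sums to 100% wherever any slope is nonzero.

Note that tree ensembles fitted to perfectly additive responses retain
a small spurious non-additivity (H of a few percent on dense, noise-free
fits), and a response clipped at 0 or 1 is genuinely non-additive —
additivity checks therefore use generating functions whose range stays
inside (0, 1).

## Space-time application

Backward predictive runs keep climate predictors dynamic and freeze
forest and landscape predictors at their 2009–2018 means (multi-temporal
monitoring of stand structure is not assumed). PFT-specific predictions
are averaged with cover-fraction weights; cells under 0.1 forest cover
are masked. Prediction uncertainty is the per-tree spread over the
ensemble divided by √(number of trees). Anomaly predictors are computed
against the mean of the early baseline years (≤ 1990). Trends are OLS
slopes (a Theil–Sen alternative is provided) with two-sided
Mann–Kendall significance — tie-corrected variance, continuity-corrected
normal approximation. Factorial attribution reruns prediction with
exactly one climate driver dynamic; the driver with the largest absolute
trend dominates (all drivers by default; a significant-only option
restricts to Mann–Kendall p < 0.05). Zonal statistics are forest-area
weighted with 100-sample percentile-bootstrap CIs, and an envelope mask
(training ranges of long-term temperature and climatological
precipitation) bounds extrapolation.

## Overall vulnerability index

Disturbances are treated as independent, mutually non-exclusive, and
homogeneously spread within a cell, so the combined loss is the
inclusion–exclusion union, `1 − Π(1 − p)`. Contribution shares are each
disturbance's proportion of the sum of individual losses — this
decomposition reproduces the published share figures from the published
means; an exact Shapley decomposition of the union is available behind a
flag. The space-time integrated index multiplies the min–max-normalized
current index and trend over unmasked cells (a constant factor
normalizes to zero, with a warning). Cross-disturbance interactions
(windthrow priming bark-beetle outbreaks, insect-killed fuel feeding
fires) are explicitly out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes
while remaining fully known:

* **Landscape** — spatially smooth Gaussian fields for cover and all
  static predictors (registry means/scales chosen as typical for
  temperate European forest landscapes: e.g. tree age 80 ± 30 yr, stand
  density 400 ± 150 trees/ha, cover ~60 ± 20%); mutually exclusive
  loss/gain pixel assignment (8% / 5%); per-pixel Dirichlet PFT mixes
  scaled to total cover. By default the 2010 biomass is pinned to
  constant true densities (ρ_loss = 2.0, ρ_gain = 0.8 t/ha/%) on the
  change pixels, making the reconstruction round trip exact and the
  loss density stochastically dominant over the gain density, as old
  forest versus regrowth should be.
* **Climate** — per-variable climatology + configured linear trend +
  AR(1) noise (ρ = 0.3; reanalysis series are temporally
  autocorrelated), anomalies against the ≤ 1990 baseline.
* **Response** — `clip(base + Σ wᵢ zᵢ + Σ c_ij zᵢ z_j + ε, 0, 1)` on
  registry-standardized predictors. Default truths use three informative
  and three nuisance predictors, noise 0.05, and intercepts at the
  published continent-mean vulnerabilities (fires 0.26, windthrows 0.30,
  insects 0.20); signal weights ~0.1 give a signal-to-noise ratio at
  which the published explained-variance levels are attainable.
* **Patches** — axis-aligned cell rectangles; realized losses edit the
  biomass stack multiplicatively (post-event years scaled by
  `1 − loss`), so the downstream loss computation recovers the truth
  exactly on clean footprints. Placement rejects footprints overlapping
  cover-change pixels or another patch's attribution window; when a
  dense configuration exhausts capacity, patches are placed anyway and
  flagged `clean=False` — attribution noise of the kind real records
  contain. A `truth.json` sidecar stores every generating parameter so
  tests never reverse-engineer them.

What the generator does **not** emulate: disturbance meteorology and
spread, insect population dynamics, geographic realism, spatially
correlated *response* noise, and observation error in the biomass map.
Passing tests therefore demonstrate that the pipeline recovers known
structure under its own assumptions — not that those assumptions hold
for any particular real landscape.

## Problem sizes and numerical choices

The demonstration pipeline runs a 32×32 grid, 40 climate years and 1500
patches (about four minutes on one CPU); model-recovery studies use
5000 tabular records; interaction studies use dense 20 000-record
noise-free fits. H/ΔP row subsampling defaults to 500 rows. Degenerate
inputs are handled explicitly: constant features z-score to zero, a
zero-range PC axis collapses to one bin, constant series get trend 0
with p = 1, a flat two-way surface reports H = 0, an all-zero slope set
yields missing `Z_marg`, and an empty pre-event biomass window is an
error rather than a zero.

## Known limitations

* Losses at a patch are attributed wholly to the recorded disturbance;
  co-occurring events within the attribution window contaminate records
  (flagged in synthetic data, unknowable in real data).
* The binned-resampling step needs large record counts; the pipeline's
  documented fallback changes the estimator at small n.
* OVI independence is an upper-bound-free simplification; interacting
  disturbances can exceed it.
* The envelope mask bounds, but cannot eliminate, tree-ensemble
  extrapolation artifacts (flat response beyond the training hull).
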