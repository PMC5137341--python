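# Methods

## Scope and model

`canopycarbon` estimates forest carbon density tree by tree.  The pipeline
assumes a height-normalized ALS point cloud (heights above ground, small
negative noise tolerated to −0.5 m), a co-registered hyperspectral
reflectance cube in the same projected metric CRS, and coefficient tables
for the two allometric models below.  All planimetric units are metres,
stem diameters cm, biomass kg, carbon densities Mg C ha⁻¹; unit
conversions happen only at module boundaries and are asserted in tests.

### Crown delineation

The canopy height model (CHM) takes the maximum return height per cell;
empty cells are filled with the mean of their non-empty 8-neighbours (0 if
isolated), preventing spurious pits without a full pit-filling pass.  The
default resolution is 0.5 m — at ~48 pulses/m² the expected count per cell
is ~12, so empty canopy cells are rare (<1%, checked by simulation).  The
default low-pass filter is a single 3×3 mean pass; a 3σ-truncated,
edge-renormalized Gaussian is available.  Both are edge-aware convex
smoothers, so they cannot create new extrema.

Tree tops are CHM cells that strictly exceed every cell whose centre lies
within a circular window (default diameter 2.5 m) and that exceed the
small-tree cut-off (default 2 m).  Flat plateaus spanning the entire
window are not seeded (a constant surface has no trees); a plateau that
stands above its surroundings seeds only its lexicographically first cell,
keeping the operation deterministic.  Crowns grow from seeds in
synchronous rounds: a 4-neighbour cell joins when its height deficit
relative to the *seed apex* (a literal reading; not a running maximum) is
below both a fraction of the apex (default 0.45) and an absolute bound
(default 6 m).  A cell claimable by two crowns in the same round goes to
the higher apex, ties to the smaller seed id — deterministic and
independent of seed order; raising either threshold can only enlarge
regions (verified as a property test).  The window size, cut-off and both
thresholds are user-set parameters with no universal values; the defaults
are plausible for Alpine conifer stands and are exposed everywhere.

Final crowns are 2-D convex hulls of each region's first returns after
removing points at or below the low-point cut-off (default 2 m); regions
with fewer than three non-collinear surviving points are dropped with a
warning.  Crown height is the 99th percentile of those first returns,
computed by linear interpolation between order statistics — the percentile
definition is pinned because different conventions shift heights by
several centimetres.

### Matching and delineation accuracy

A field stem is inside a crown when its position lies in the polygon
(boundary inclusive).  A crown with one stem pairs with it; with several,
the stem whose measured height is nearest the crown height wins (ties:
larger DBH, then smaller id).  Crowns pair greedily in id order, each stem
at most once.  DET = % of stems matched, OE = 100 − DET, CE = % of crowns
left unmatched, AI = 100 − (OE + CE).  Per-class tables bin stems by
measured DBH (default edges 10…80 cm); an unmatched crown is attributed to
the class of its *own estimated* DBH, the only DBH it has.

### Species recognition

Each pixel spectrum is divided by its band sum (it then sums to 1),
removing illumination and mosaicking brightness differences; zero-sum
pixels become nodata.  Within each crown, pixels at or above the crown's
median pre-normalization brightness are kept as sunlit (the quantile is
configurable; crowns with <2 pixels keep all).  Class separability is the
Jeffries–Matusita distance JM = 2(1 − e^(−B)) with B the Gaussian
Bhattacharyya distance; covariances get a diagonal load of 10⁻⁶ × mean
variance before inversion because per-class pixel counts are often small.
Feature selection is Pudil-style SFFS — greedy additions maximizing the
mean pairwise JM (minimum pairwise available as an option), each followed
by conditional backward removals kept only while the criterion improves;
ties resolve to the lowest feature index, making the search deterministic.
The pixel classifier is a one-vs-one soft-margin SVM with RBF kernel,
standardized inputs, and C ∈ {10⁻¹…10³}, γ ∈ {10⁻³…10¹} chosen by seeded
stratified 5-fold cross-validation; the crown's 99th-percentile ALS height
joins the selected spectral features.  Crown labels are the modal pixel
prediction; ties go to the label with the greater mean decision
confidence, then lexicographic order.

Confusion matrices are oriented rows = predicted, columns = reference, so
producer's accuracy (reference recall) is column-based and user's accuracy
row-based; average accuracy is the unweighted mean of producer's
accuracies and kappa the usual chance-corrected agreement.

### Allometry

Stem diameter: DBH = ε·H^ρ·(1 + ϑ·CA).  Fitting minimizes the τ-pinball
loss (default τ = 0.5, i.e. median regression — resistant to the
heteroscedastic scatter of diameter–height data) with a smoothed absolute
value (√(r² + ε²) − ε, ε annealed 1 → 0.01) optimized by Nelder–Mead from
eight starts (log-linear regressions at several ϑ guesses plus fixed
fallbacks), then scored under the exact loss.  Standard errors come from a
seeded nonparametric bootstrap (default 200 resamples; set `n_boot=0` to
skip).  Species with ≥100 samples get their own row in addition to the
pooled "All" row.  The packaged Alpine coefficient table is the default.

Biomass: AGB = α·WD^β·(DBH − d0)^γ·H^δ, with β = 1 (biomass proportional
to wood density) and δ typically in 0.83–1.34.  Regional stem-volume
coefficient tables are not redistributable, so the packaged table is a
synthetic placeholder (flagged in its `source` column) meant to be
replaced; all tests use synthetic coefficient sets.  Stems at or below d0
get zero biomass with a warning.  Carbon fractions default to 0.5
(conifers) and 0.48 (angiosperms).

### Carbon aggregation

Plot carbon density sums member carbon over the circle area (stem position
for field trees, seed position for crowns).  The hidden-tree correction is
the proportional least-squares slope m = Σ(field·ars)/Σ(ars²) of field on
airborne densities — the minimal estimator for a relation reported as a
pure multiplier; the fit also reports post-correction RMSE and R² with and
without intercept, since a proportional relation leaves the intercept
question open.  Carbon rasters assign each crown's carbon wholly to the
cell containing its seed rather than splitting polygons across cells:
under the tree-centric view the only edge error is whether a tree centre
falls inside a boundary, and seed assignment conserves total carbon
exactly at every cell size (area-weighted splitting would too, but blurs
per-tree attribution).  `rmse_vs_plot_size` samples ≥100 seeded random
circular plots per area and reports 100·RMSE/mean density of the corrected
airborne estimate against truth.

## Synthetic data: what it emulates, what it does not

The simulator reproduces the statistical regime the pipeline assumes:
stem diameters 3.5–121 cm, heights 1.5–48.8 m, crown areas 1.5–55.4 m²
(the `alpine_default` scenario enforces these ranges), ~48 pulses/m² with
up to 4 returns, 1–2% DBH and 5% height measurement error, and 5 species
with configurable spectral separability.  Trees are placed by hard-core-
inhibited Poisson darts (or a jittered grid in `separable_stand`); crowns
are paraboloids of revolution — the simplest surface with a unique apex a
region grower can segment.  Heights and crown areas are drawn first and
DBH follows the truth coefficients with 15% lognormal scatter, so refits
recover the generating values.  Understorey trees (3–9 m) are placed
beneath random crowns until they hold a prescribed carbon share (default
19%), giving the hidden-tree multiplier the known truth 1/(1 − share) ≈
1.23.  Spectral classes sit at regular-simplex vertices over a smooth base
spectrum with isotropic covariance, so every class pair has *exactly* the
target JM; crown-edge pixels are darkened by a shading factor to exercise
sunlit extraction.

Deliberately absent: radiative transfer, topography (ground is flat and
heights are above-ground by construction), full-waveform returns, crown
asymmetry and mutual shading, spatially correlated species composition,
and co-registration error between cloud and cube.  Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour under the
assumed regime, not performance on real multi-layered stands — on real
data the delineation thresholds require tuning and the hidden-tree
multiplier local calibration.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small scenes: 80×80 m
separable stands (~100 trees, ~350k returns), 1-ha mixed stands for the
multiplier experiments (30 validation plots of 15 m radius), 1000-triple
refits repeated over 20 seeds, and 8–12-pixel grids for the brute-force
oracle comparisons.  Degenerate inputs are handled explicitly: empty
clouds and zero-sum pixels are errors or nodata, collinear hull inputs and
sub-3-point regions are dropped with warnings, singular covariances are
diagonally loaded, all-zero airborne densities refuse a multiplier.
Percentile interpolation, tie-breaking rules and the covariance load are
pinned above because each one changes third-decimal results.

## Known limitations

LAS support covers the 1.2 point formats 0/1 fields the pipeline uses
(XYZ, return counts, ground class); no waveform, extra-bytes or CRS
reprojection.  The height-difference rule compares against the seed apex,
so very asymmetric crowns may truncate on their low side.  The SVM grid is
fixed rather than adaptive; SFFS cost grows quadratically with candidate
features.  The multiplier is a single stand-level constant — forests
differing in understorey structure need separate calibrations.
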