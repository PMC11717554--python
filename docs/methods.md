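# Methods

This note documents the models implemented in `poppyspread`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about behaviour on real data.

## Establishment kernels

An *establishment kernel* (effective dispersal kernel) is the probability
density of the distance z between a source individual and a newly
established individual; it folds dispersal and establishment success into
one distribution. Distances are constructed from a single abundance survey
under two source assumptions:

* **local** — for every individual, the Euclidean distance to the nearest
  other individual. Records carry an abundance k (individuals within the
  50-cm recording radius), and are expanded to k co-located individuals;
  a nearest-neighbour distance below 0.25 m (half the recording radius,
  i.e. the data's spatial resolution) is floored at 0.25 m so that
  log-supported families keep finite likelihoods.
* **trail** — for every off-trail individual, the distance to the nearest
  on-trail individual; the trail population is treated as the source pool.

Candidate families are scipy location–scale distributions with an optional
shape parameter: log-normal, Cauchy, exponential, exponential power,
chi-square, Rayleigh. "Exponential power" here is the density
b·x^(b−1)·exp(1 + x^b − e^(x^b)) on x ≥ 0 (scipy's `exponpow`), noted
prominently because the name is used for several unrelated families in the
literature.

Parameters are estimated by **maximum likelihood**; ranking uses the sum of
squared errors between the empirical histogram density (Sturges bins on
[0, max distance], density-normalised) and the fitted pdf at bin centres,
with BIC = k·ln n − 2·logL as tiebreaker and family name as the final
deterministic tiebreak. ML estimation is statistically better behaved than
direct SSE minimisation; for fidelity experiments against SSE-minimising
fitters an `estimation="sse"` mode refines the MLE by Nelder–Mead on the
histogram objective.

Mean establishment distances use closed forms (log-normal
loc + scale·e^(σ²/2), exponential loc + scale, Rayleigh
loc + scale·√(π/2), chi-square loc + df·scale); the Cauchy has no mean and
reports its location (median) instead; the exponential power integrates
z·pdf(z) by adaptive quadrature (tolerance 1e-8). Skewness is the analytic
standardised third moment where defined (undefined for the Cauchy, which
raises), or a seeded sample-moment estimate.

## Spread simulation

State: a boolean occupancy grid at 5-m resolution over 1928–2018 (both
configurable). Each year,

1. the fitted 1-D kernel is discretised on the cell grid: the weight of a
   cell at centre-offset distance z is pdf(z)·Δ with Δ the cell size,
   truncated at the kernel's 0.99 quantile (radius capped, with a warning,
   for heavy tails such as the Cauchy whose high quantiles diverge). The
   centre cell is evaluated at z = Δ/2 so densities with a pole at zero
   stay finite. Weights are rescaled only if their sum exceeds 1.
   Interpreting the 1-D distance density directly as a per-cell annual
   establishment probability along any bearing is a modelling choice; a
   ring-corrected mode (divide by 2πz, multiply by cell area) is exposed as
   a flag for sensitivity analysis.
2. the establishment probability field is the FFT convolution of the
   occupied state with the kernel. Under the **trail-effect** scenario the
   trail kernel is additionally convolved with the occupied-AND-on-trail
   state, and the two fields combine as independent sources:
   P_e = 1 − (1 − P_local)(1 − P_trail), which stays in [0, 1] without
   ad-hoc capping.
3. an unoccupied, suitable cell establishes iff P_e > T_e with
   T_e ~ Uniform(0, 1) drawn independently per cell per year (strict
   comparison; the boundary has measure zero). Occupied cells never revert.

Suitability excludes water and cells above an elevation threshold (default
137 m, the highest observed occurrence; `elevation_threshold` recomputes it
from data). The trail-source band is the set of cells whose centre lies
within half a *mask width* of a trail polyline; the simulator uses mask
width = cell size (5 m) so the band is contiguous at grid resolution,
whereas the survey-plot default elsewhere is the 2-m plot width — a 2-m
band on a 5-m grid leaves gaps between cell centres and would turn the
corridor off for purely numerical reasons.

Replicate k runs on its own RNG stream seeded base_seed + k. Arrival maps
record the first establishment year per cell; the replicate mean ignores
replicates that never colonised a cell (a colonised-replicate count layer
is also provided). Model skill against a presence-only survey is the
sensitivity TP/(TP+FA), evaluated on square blocks (1 km for systematic
grid surveys; the block size is a parameter because the published
evaluation unit is not stated): an observed block counts as TP if any
replicate-majority-occupied cell falls inside it by the survey year.

## Density attribution

The occurrence density surface is a 2-D Gaussian KDE evaluated at cell
centres. Scott's rule follows the `gaussian_kde` convention (kernel
covariance = sample covariance × n^(−1/3) in two dimensions); a scalar
bandwidth in metres is available, and required when the points are
degenerate. The surface is min–max normalised — max exactly 1 — rather than
integral-normalised, because the GLM needs a bounded response.

The GLM regresses the normalised density on z-scored distance from the
station, distance to the closest trail, elevation, and the station×trail
interaction (product of the two z-scores). Both a gaussian and a poisson
family are implemented: field practice is ambiguous about which is
appropriate for a bounded density response, so neither is asserted as "the"
model. Explained variance is the classical adjusted R² for the gaussian
family and the adjusted McFadden pseudo-R², 1 − (logL_full − k)/logL_null,
for the poisson family (McFadden's ratio is not meaningful for gaussian
least squares, so the two are labelled distinctly). Partial R² per
predictor drops that predictor, refits, and reports
(SSE_reduced − SSE_full)/SSE_reduced (deviance analogue for poisson).
Spatial autocorrelation corrections are out of scope: this is an ordinary
GLM, and its standard errors should be read accordingly.

The paired on-trail vs off-trail abundance comparison is a two-sided
Wilcoxon signed-rank test (zero differences dropped; exact null for small
samples without ties, tie-corrected normal approximation otherwise).

## Terrain preference

Brightness is the Rec. 709 relative luminance Y = 0.2126R + 0.7152G +
0.0722B on [0, 1]-scaled channels (weights configurable). The
randomisation test shifts the entire observed point pattern rigidly by
(dx, dy), each ~ Uniform(−10 m, +10 m) independently (the signed reading of
"uniform in both directions": unsigned shifts could never re-centre the
pattern). A shift that moves any point off the raster is rejected and
redrawn — rejection keeps the admissible shift distribution uniform,
whereas clamping would pile mass on the boundary — with an error after 10⁴
fruitless draws. Iteration 0 is the observed pattern and counts itself in
p = #{medY_i ≥ medY_0}/n, so the estimator is conservative (p ≥ 1/n). The
rigid shift preserves every pairwise distance, so the test isolates the
pattern–terrain association from the pattern's internal clustering, and
the median statistic makes p invariant under monotone rescaling of
luminance.

## Synthetic data generator

`synth` emulates a coastal strandflat study area at 5-m resolution
(default 240×240 cells, 1.2 km side — a deliberately scaled-down study
area):

* **DEM**: a west-to-east coastal gradient (≈ −6 to 49 m) plus sinusoidal
  beach-ridge relief (amplitude 4 m, wavelength 180 m) and smoothed
  Gaussian noise (sd 3 m), clipped to [0, 150] m. The sea is the western
  band below the 0-contour of the smooth component only (small-scale
  relief never creates isolated sea pockets inland); 2–5 circular lakes
  (radius 15–40 m) are carved into low ground (< 25 m), keeping all water
  below 60 m elevation.
* **Station and trails**: the station is the first persistent-land cell
  scanning inland at 60% of the grid height. Two trails leave it — "south"
  along the coast-parallel ridge zone, "east" along the shore — with 60-m
  vertex spacing, gentle sinusoidal wander and per-vertex jitter; vertices
  are snapped inland (eastward) onto land so trails never run through
  water.
* **Ground truth**: the spread simulator itself, run under the trail-effect
  scenario with the configured true kernels. The defaults are the published
  best fits — local log-normal(0.8611, −0.0799, 1.3177) and trail
  log-normal(0.5760, −9.9562, 33.6560) — so closed-loop recovery tests run
  under the study's own conditions. Reusing the simulator as the truth
  generator makes recovery tests circular *by design*: the fitted kernels
  are "effective dispersal" kernels, and simulating establishment directly
  matches that semantics.
* **Surveys**: systematic block surveys record one presence at the centre
  of every block containing an occupied cell (1-km blocks at full scale;
  250-m blocks suit the default synthetic extent). The transect sampler
  walks the south trail placing T-shaped transects every 50 m (2×50 m
  trail plot, 2×100 m perpendicular off-trail plot, eastward only — the
  west side is treated as a protected area) and stops after 5 consecutive
  empty trail plots. Cluster counts per transect are Poisson with mean
  14 × local smoothed occupancy (≈ 28 individuals per transect at
  saturation, matching the contemporary survey's 718 individuals over 26
  transects); each cluster lands on the trail plot with probability 0.869
  (the observed on-trail share) and carries abundance 1 + Poisson(1).
  Off-trail cluster distances decline exponentially (scale 30 m, truncated
  at 100 m). Detection within plots is perfect, mirroring the census
  treatment of the field protocol.
* **UAV scene**: a 10-cm luminance image along the first ~120 m of the
  south trail; background ≈ 0.25 with smooth and fine-grained texture,
  gravel patches ≈ 0.6, trail band ≈ 0.8. RGB is synthesised by blending a
  grey (gravel) and a green (vegetation) hue whose Rec. 709 luminance both
  equal 1, so relative_luminance(RGB) reproduces the luminance channel
  exactly. Poppy positions are drawn with probability ∝
  exp(strength × luminance) from pixels inset 10 m from the edges (so
  every test shift is admissible); strength 0 is the exact null of the
  randomisation test, and the default strength 4 produces a clear terrain
  preference.

What the generator does **not** emulate: imperfect detection, observer
variation in the historical records, demographic processes (mortality,
seed banks, density dependence), anisotropic dispersal (wind), radiometric
artefacts in the orthomosaic (shadows, exposure seams), or the actual
geography of any real site. Passing tests therefore demonstrate that the
estimators and the simulator are internally correct and well calibrated
under the stated model, not that the model captures every process in the
field data.

## Numerical choices and degenerate inputs

* Rasters are row-major with row index increasing northward; cell extents
  are half-open and boundary points belong to the higher-index cell; cell
  membership is decided by cell centres. ESRI ASCII and GeoTIFF files
  store rows north-down and are flipped on read/write.
* FFT convolution is required (by test) to match direct spatial
  convolution to 1e-9; KDE matches the explicit Gaussian sum to 1e-10.
* All-identical points make Scott's bandwidth singular — a scalar
  bandwidth must be supplied. All-zero paired differences make the
  Wilcoxon test undefined — an error, not a p-value of 1.
* Kernel fits require n ≥ 10 distances; families whose fit fails are
  reported and skipped, and only the failure of every family is fatal.
* Simulation replicates are seeded base_seed + k; every stochastic routine
  takes an explicit seed and is bit-reproducible.

## Problem sizes used in the checks

The end-to-end checks run on deliberately modest sizes chosen to exercise
every code path at full statistical strength: a 200×200-cell landscape over
90 simulated years with 40 paired-seed scenario comparisons; 400
independent terrain/placement realisations for the type-I calibration of
the randomisation test (500 iterations each) and 60 for its power on the
bright-stripe fixture (1000 iterations each); 10⁴ draws for scale
recovery, 50 seeds × 500 draws for mean recovery, and 10⁴ grid cells for
GLM coefficient recovery.
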