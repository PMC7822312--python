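# Methods

This note documents the models, algorithms and numerical choices behind
`cpforage`, and what the synthetic-data suite does and does not demonstrate.

## Track QC and trip definition

Raw deployments are cleaned in a fixed order: rows with unparseable
timestamps or out-of-range coordinates are dropped at read time; fixes with
missing time or in the Northern Hemisphere are removed; exact
(timestamp, lon, lat) duplicates are removed; same-timestamp conflicts keep
the first fix (logged). The speed filter is a **single forward pass**: a fix
is dropped when the great-circle speed from the last *retained* fix exceeds
10 km/h (Adélie penguins swim at about 2 m/s = 7.2 km/h, so faster
apparent movement is positional error). A forward pass is order-stable and
idempotent, unlike global re-filtering.

Trips are maximal runs of fixes farther than a **colony radius**
(default 0.2 km, configurable) from the colony (140.01° E, 66.66° S), each
bracketed by its last at-colony fix (departure) and first at-colony fix
(return). The radius automates the otherwise manual removal of at-colony
points; 0.2 km comfortably exceeds GPS noise yet is far smaller than one
travel step. A recording that ends at sea is completed with a virtual
colony fix at the nest-check return time when **strictly more than 70%** of
the nest-check trip duration was recorded (a fraction of exactly 0.70 is
discarded), otherwise discarded. Retained trips keep their chronological
index, so a discarded trip leaves a gap that downstream pairing respects.

Resampling places fixes at departure + k·20 min with linear interpolation
of lon/lat in time. At these trip scales (< 150 km) linear vs. great-circle
interpolation differs by far less than GPS noise; this is a documented
approximation. The grid never extends past the return time; trips shorter
than one step keep their endpoints and are flagged.

All distances are haversine on a sphere of radius 6371.0088 km; bearings
are initial great-circle bearings, degrees clockwise from north in
(-180, 180], positive eastward. Published summaries of this system contain
both sign conventions for bearing; magnitudes are unaffected and the
folded bearing |θ| ∈ [0, 180] used for variance components is invariant to
the choice. The fold is justified because observed bearings span well under
half the circle (44% between −71.8° and +87.8°), so the trait can be
treated as linear rather than circular.

## Phase segmentation

Pooling every fix of every trip onto (x = % trip duration elapsed,
y = % of maximal colony distance) yields a bell-shaped cloud. The phase
boundaries are estimated by a **continuous two-breakpoint piecewise-linear
least-squares fit**: for fixed (f₁, f₂) the model is linear in the basis
{1, x, (x−f₁)₊, (x−f₂)₊}, so each candidate pair costs one 4×4 solve. The
grid (default 0.5% spacing, f₁ < f₂, at least 3 points per segment) is
scanned exhaustively; Gram matrices for all pairs are assembled from suffix
sums of the sorted profile, making the full scan O(n log n + m) for m grid
pairs. This deterministic fit replaces a Bayesian multiple-changepoint
regression: it is reproducible, oracle-verifiable (the test suite checks
exact agreement with a brute-force enumeration), and adequate for a
two-knot model. Breakpoint uncertainty is reported as the half-width of the
breakpoint range over all grid pairs whose RSS is within 5% of the minimum
— an RSS-profile interval, not a posterior.

Fixes are weighted equally (trips with more fixes contribute more points);
trip-equal weighting would require per-trip weights and is not what the
pooled profile represents. Boundary fixes exactly at f₁ or f₂ belong to the
central phase. The shipped defaults f₁ = 31.2, f₂ = 69.7 are the
population-calibrated fallback used when no pooled fit is requested;
pipeline runs with `phase_mode = fit` estimate them from the data.
Validation compares per-phase kinematics (distance, mean speed, sinuosity =
path length / straight-line displacement, undefined for closed segments)
with Wilcoxon rank-sum tests: a correctly placed central phase shows slower,
more sinuous movement than both transits.

## Sea ice

Daily concentration fields are regular lon/lat grids (nominal 6.25 or
12.5 km cells) read from NetCDF (`sic(time, lat, lon)`); out-of-range
values are masked on load. Extraction conventions: a fix takes the value of
its **containing cell** (no interpolation; west/south cell edges
inclusive); regional means average unmasked cell centers inside a polygon,
then average over the days of the window; masked cells are excluded, never
imputed. Coarse-to-fine regridding is nearest-neighbour block refinement,
so sampling the fine field anywhere equals sampling the coarse field — an
invariant the tests assert.

Two averaging scales: the fixed study box (64–67° S, 137–143° E) and the
**annually prospected area**, operationalized as the convex hull of all
retained fixes of a season (the "annual maximal extent" has no stated
operational definition; the hull is the stated proxy). Areas use a
spherical Lambert azimuthal equal-area projection centred on the hull, so
they are equal-area by construction; published area figures are
projection-dependent and not comparison targets. A hull smaller than one
grid cell (possible in small simulated cohorts) is buffered by one cell
before regional averaging, with a log notice.

For a consecutive trip pair, `mean_sic_pair` averages the prospected area
over the union of the two trips' date spans; the alternative reading (mean
of the two trip means) is available as `pair_mode="mean_of_means"`.
`sic_difference` = mean(trip n) − mean(trip n+1); positive means the ice
receded between trips.

## Repeatability

Each trait y (log total duration, log total distance, log maximal distance
— log-transformed for residual normality; folded bearing and central-phase
ice concentration untransformed) is modelled as

y_ij = x_ij'β + a_i + e_ij,  a_i ~ N(0, σ²_A),  e_ij ~ N(0, σ²),

with bird identity the grouping factor. The solver profiles the likelihood
in the variance ratio λ = σ²_A/σ²: given λ, GLS estimates and the profiled
σ² are closed-form via per-group sufficient statistics, leaving a bounded
1-D optimization in log λ (with an explicit σ²_A = 0 boundary check). REML
is used for reported variance components; ML refits of the same structure
supply AICs so fixed-effect structures are comparable. The suite verifies
agreement with statsmodels MixedLM to four decimals; the specialized solver
exists because the bootstrap and recovery suites need tens of thousands of
refits (~1 ms each).

Backward selection starts from year × days-since-peak-hatch (year
categorical, timing continuous; interaction only with both mains): at each
step the candidate drop with the best AIC is accepted unless the larger
model is better by more than 2 AIC units (parsimony rule). R is categorized
low (R < 0.25), moderate (0.25 ≤ R ≤ 0.5, the boundary assigned to
moderate), high (R > 0.5). Uncertainty: parametric bootstrap (default 1000
draws; simulate from the fitted model, refit, recompute R), reporting the
bootstrap SD and 2.5/97.5 percentile interval. Coverage of the 95% interval
is verified at ≥ 90% over 50 replicates in the acceptance suite.

At 100 birds × 5 trips the sampling SD of R̂ is itself ≈ 0.05 (at R = 0.4),
so recovery is assessed as mean absolute error over 50 replicates (< 0.05
across true R ∈ {0.1, 0.25, 0.4, 0.6}), not per single draw.

## Site fidelity and inference

NND(focal, previous) = mean over focal central-phase fixes of the
great-circle distance to the nearest previous central-phase fix —
asymmetric by construction (focal = later trip). Nearest neighbours are
found exactly by embedding fixes on the unit sphere and querying a k-d tree
on chord distance (monotone in the central angle), then converting back to
km; the tests require exact agreement with the quadratic all-pairs minimum.
Pairs are formed only between trips with consecutive indices within a bird
— a discarded intermediate trip breaks the chain (`allow_gaps=True` chains
retained trips instead). Central phases with fewer than 2 focal fixes are
skipped.

Inference operates on log(NND); back-transformed curves are exp of the
link-scale fit. The year model is OLS on year (first season = reference).
The year × timing model adds estimated marginal means per season at the
grand-mean timing and all pairwise year contrasts with a Tukey
(studentized-range) adjustment at the model's residual df; its family-wise
type-I error was measured at 4.6% over 2000 null replicates. Seasons with
fewer than 3 records are dropped from the contrast family.

The smooth NND–ice relationship is a **P-spline mixed model**: cubic
B-spline basis (default dimension 10) with a second-difference penalty,
reparametrized so the penalty null space (constant + linear) enters as
fixed effects and the penalized range space as an iid random block,
alongside a bird random intercept. Both variance parameters are chosen by
REML (Nelder-Mead on the profiled criterion). Effective degrees of freedom
come from the trace of the smoother matrix over the smooth's columns
(edf = 1 when the wiggly part shrinks away); the 95% band uses the Bayesian
posterior covariance of the coefficients. REML smoothing-parameter
estimates are variable when the truth is linear — edf collapses to exactly
1 for about half of simulated datasets and wanders to 2–4 for the rest
while the slope is recovered throughout; tests therefore judge edf across
seeds. A rank-deficient basis at small n falls back to a straight line with
the random intercept (flagged).

## Synthetic study generator

`simulate_cohort` builds each trip in a local tangent plane around the
colony: outbound transit to a foraging patch at 5 km/h with lateral jitter
(tapered within 1 km of the colony so the colony radius is crossed exactly
once), a slow (1.5 km/h), high-turning random walk at the patch for the
central (f₂−f₁)% of the trip, inbound transit home, fixes every 5 min plus
colony dwell fixes between trips. Trip timing is set so the true phase
boundaries sit at the configured fractions (default 30/70% of trip
duration). Per-bird traits (log patch distance, heading) are drawn from
normal population distributions; the per-trip realized trait is the bird's
value plus a within-individual draw, so the configured variance
decomposition — and hence the true repeatability
R = σ²_between/(σ²_between+σ²_within) — is what the trips express.
Defaults mirror the reference cohort: 129 birds across six seasons with the
observed distribution of 2–9 trips per bird, median patch distance 20 km
(R ≈ 0.38 for log distance, ≈ 0.41 for heading).

`fidelity_mode` controls site fidelity: *faithful* birds anchor every trip
to their own patch ray (so consecutive central phases are close); an
*explorer* prospects a fresh patch each trip — distance drawn from the
population distribution, heading uniform over the accessible arc (default
−72° to +88°, the observed population bearing range) — carrying no
individual signal (true R = 0) and yielding systematically larger NND.
Truncated recordings (probability 0.15, recorded fraction uniform on
0.5–0.95) **terminate the deployment**, as a dead logger would; this
exercises both virtual completion (> 70% recorded) and discarding.

Ice fields are a south-to-north concentration gradient (coastal 80% to
offshore 5%) over a grid that extends one margin beyond the 64–67° S /
137–143° E study box, with smooth spatial noise, daily multiplicative
recession (1%/day) and a masked land cell at the colony. With noise off,
the regional mean follows the closed form mean₀ · (1−r)ᵈ and is
non-increasing.

What the generator does **not** emulate: GPS outliers and device-specific
error structure (tests inject spikes explicitly), tides/drift and ice
advection, diurnal haul-out behaviour, prey-driven patch relocation within
a trip, and correlation between ice conditions and trip geometry. Passing
tests therefore demonstrate the estimators' correctness and calibration
under the stated statistical structure, not robustness to every field
artifact.

## Problem sizes and determinism

The test and acceptance suites run cohorts of 14–30 birds for end-to-end
checks, 100 birds × 5 trips for variance-component recovery (50
replicates), 200-draw bootstraps for coverage, and 300–1000 replicates for
null calibration — sizes chosen so every stochastic claim is judged at a
resolution where its sampling noise is small relative to the tolerance.
All randomness flows from explicit seeds; identical seeds reproduce
byte-identical generator output and pipeline artifacts.
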