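# Methods

This note documents the models and procedures implemented in `circuitmig`,
the defaults and why they were chosen, what the synthetic study system does
and does not emulate, and the numerical decisions a maintainer would need
to know.

## Migration delimitation

Net-squared displacement is computed per track against the first fix. A
migratory track is one whose trailing-window maximum exceeds four times the
leading-window median plus 1 km²; non-migratory tracks raise an explicit
"no migration detected" outcome and are skipped with a log entry. The
plateau level is the median of the top quartile of the series, and the
window runs from the last fix before the series exceeds 5% of the plateau
to the first fix at or above 95% — a deterministic surrogate for the visual
endpoint picking used in field studies, chosen so every run is exactly
reproducible. Both fractions are exposed (`low_frac`, `high_frac`).
Endpoints are always recorded fixes, never interpolated positions, because
they become circuit terminal cells. No automated rule can claim equivalence
to expert visual assessment; the 5%/95% rule is the package's own
convention.

## Covariates

* **Terrain ruggedness** is the vector ruggedness measure: unit surface
  normals from Horn 3×3 finite-difference slope components (the common DEM
  convention; flat cells take normal (0,0,1) so aspect is never undefined),
  summed over a 3×3 window, `VRM = 1 − |R|/9 ∈ [0, 1]`. Windows touching
  the raster edge or nodata yield nodata, not zero. The layer is
  standardized (mean 0, sd 1) after aggregation.
* **Road decay** is `exp(−α/d)` with `d` the exact point-to-segment
  distance (km) from each cell centre to the nearest road, defined as 0 at
  `d = 0` (the limit). Distance is computed at the native grain and
  block-averaged to the analysis grain, so the decay can be re-evaluated
  for any α without re-measuring distances.
* **Rivers** rasterize by any-touch at half-cell densification;
  **land cover** aggregates by modal class with open ground (class 0) the
  reference; elevation-derived layers aggregate by block mean. The analysis
  grain defaults to 1 km.

## Resource selection

Used fixes (inside the detected migration window) are contrasted with 20
available points per used location sampled uniformly over the study-area
rectangle; available points inherit the animal-year of their used point so
grouping covers both response classes. The likelihood is plain (unweighted)
binomial with logit link. The decay parameter scan fits one univariate
model per α over the fixed grid (1–20 by 1, 25–50 by 5, 60–100 by 10,
150–350 by 50 — 36 candidates) plus a linear-distance model, ranked by
AICc (`−2ℓ + 2k + 2k(k+1)/(n−k−1)`); the covariate structure is chosen from
the 16-model factorial set (land cover moves as one three-indicator group).
A scan precondition of at least one candidate (rather than two) is used so
the degenerate single-candidate case is well defined with weight 1.
Candidates whose fit fails — including separation, detected both from the
fitting exceptions and from a scale-invariant divergence check (any
coefficient contributing more than ~30 logits per covariate standard
deviation) — are dropped with a warning.

Random intercepts for animal and year-within-animal are available
(`random_effects=True`) through an in-package Laplace approximation:
penalized Newton for the joint mode of (β, u), a Nelder–Mead outer search
over the two log standard deviations, and the standard Laplace marginal
log-likelihood `ℓ(û) − ½û'D⁻¹û − ½log det(D·H_uu)`. When both variance
estimates collapse to the boundary the fit returns the fixed-effects
logistic solution exactly (a tested equivalence). The parameter count for
AICc adds the two variance components. The default pipeline runs fixed
effects: the synthetic system generates homogeneous animals with one year
each, so the variances are boundary cases by construction.

Relative habitat suitability is `hs = w/max(w)` with
`w = exp(fixed-effect linear predictor without intercept)` — the intercept
only encodes the used:available ratio and random effects are
individual-level, so neither belongs in a population map. Max-normalisation
is the minimal monotone map onto the (0, 1] domain the resistance
transforms require; any rescaling of `w` cancels.

Validation splits used points into k folds (10 by default), trains on the
rest plus all available rows, bins withheld-point scores into 10
equal-interval bins over the available-point score range, and
rank-correlates the area-adjusted used frequency (used count ÷ available
count per bin, normalized) with bin order. Road response curves come from a
parametric bootstrap of the coefficient sampling distribution (500
multivariate-normal draws from the estimate and covariance), with other
covariates at their mean or baseline — a deliberate trade of the heavier
refit-per-resample bootstrap for desk-scale runtime, recorded in the output
metadata.

## Resistance scenarios

Five links between suitability and resistance are carried in parallel:
r0 neutral (`r = 1`), r1 positive linear (`r = hs`), r2 negative
exponential (`r = (1/hs)²`), r3 negative linear (`r = 1/hs`), r4 negative
logarithmic (`r = ln(1/hs)`). `hs` is clamped below at 1e-3 before division
or log; the subsequent linear stretch of every non-neutral surface to
[1, 1000] (computed per surface over valid cells; a constant surface maps
to 1) makes results insensitive to the exact clamp — a tested property.
`r4` legitimately produces raw zeros at `hs = 1`; the stretch maps them to
the lower bound. Rebuilding with proposed roads recomputes only the road
covariate (union of existing and proposed), re-predicts `hs` with unchanged
coefficients and α, and re-applies each individual's top scenario; an empty
proposed set reproduces the baseline bitwise.

## Circuit engine

Valid cells are nodes; orthogonal neighbours connect with conductance
`2/(r_i + r_j)` and diagonals with `2/(√2(r_i + r_j))` — half-cell
resistances in series, diagonals scaled by centre-to-centre distance.
Terminal cells participate through the same rule (their own resistance is
not shorted). The grounded system is solved by sparse LU on the reduced
Laplacian; the relative residual must meet the tolerance (default 1e-8) or
the solve raises, and the maximum net nodal current at non-terminals is
reported as the Kirchhoff residual. Node current density is the half-sum of
absolute incident branch currents (each unit of through-flow counted once);
terminals report the injection, fixed at 1 unit — maps are relative, and
uniform rescaling of resistance leaves them unchanged (tested). Migration
endpoints snap to the nearest valid cell within 5 cells; snap failures and
disconnected source/ground components (reported with component sizes) skip
the individual with a log entry.

## Ranking, population maps, impact

Per individual, the five current maps are scored by summed current at the
containing cell of every in-window fix (each fix counts once; nodata fixes
contribute zero with a logged count) and sorted descending. Exact ties are
broken toward the simpler transform in the fixed order r0, r3, r1, r4, r2
and flagged. Population maps standardize each top map to sum to one before
summing, so the total equals the number of individuals and each animal
carries equal weight; map validation blocks folds by individual to avoid
leakage. Impact extraction takes all valid cells whose centres fall within
the buffer radius (20 km default) of a community point — the same index set
for both road variants, so cells are paired — and summarises
`d = (mean_with − mean_without)/sd_without` (baseline standardizer;
pooled sd available by configuration) with a 2,000-resample paired
bootstrap CI. Cell-level bootstrap is the self-contained choice; the CI is
clamped to bracket the point estimate. Boundaries classify upward:
|d| = 0.2 → small, 0.5 → medium, 0.8 → large.

## Synthetic study system

The generator emulates: smooth terrain whose roughness varies spatially
(a smoothed Gaussian field modulated by a broader envelope), wiggly river
and road polylines crossing the extent, categorical land cover with open
ground most frequent plus dense-vegetation, burn and coastal-strip classes,
community points, and seasonal migrations with the
residency–migration–residency NSD shape. Movement is a biased random walk
on the 8-neighbour lattice: step weight
`(1/resistance)^selection_strength × exp(bias × progress-to-goal)`, with
residency tethered to (and bounded by) the seasonal range and the goal bias
ramping up slowly during migration (multiplier `1 + steps/400`) so a walker
cannot stall indefinitely in a low-resistance pocket — read as increasing
directional persistence as the season advances. Collars sample the walk
rather than every move: consecutive fixes are `steps_per_fix` lattice steps
apart (default 4, nominal 8-h interval), which matters because per-step
fixes would oversample the terminals' current-density bullseyes and bias
scenario scoring. One seeded generator drives everything; identical seeds
give bit-identical landscapes and tracks.

It does not emulate: energetics, snow and ice, predation, herd demography,
fix error, collar failure, or real arctic geography. Passing recovery tests
therefore show the pipeline's inference machinery is self-consistent under
its own movement model — not that the movement model is a faithful caribou
model.

## The corridor testbed and what recovery does and does not show

Scenario-transform recovery is intrinsically hard: all three negative
transforms are monotone in suitability, so their current maps share route
locations and differ only in concentration, and the summed-current ranking
rewards whichever map's concentration best matches the walkers'. Random
landscapes frequently lack the structure that makes the five transforms
distinguishable at all. The validation experiments therefore run on a
fixed, deliberately designed suitability field (`corridor_suitability`): a
broad curving high-suitability corridor, a weaker straighter branch (so
transforms with different mid-suitability tolerance route differently),
six low-suitability discs off both routes (giving the positive-linear
scenario a distinct corridor system), and a deterministic sinusoidal
texture at the 5–10 km scale (so sharper transforms concentrate current on
narrower threads). Randomness enters through the animals, never the
landscape; walker defaults for these experiments are selection strength
1.5 and goal bias 0.6.

Under this design, tracks generated on the negative-linear (r3) and
positive-linear (r1) surfaces are attributed to their generator by a clear
plurality (typically 25–30 of 30 individuals) across walker seeds. Tracks
generated under the extreme negative transforms (r2, r4) are, at these
settings, mostly attributed to the neighbouring r3 — the ranking reliably
identifies the sign and broad regime of the suitability–resistance link
but not the exact curvature among adjacent negative transforms. This
limitation is a property of the summed-current ranking itself and is worth
bearing in mind when interpreting real rankings.

The road-impact experiment adds a road segment crossing only the main
corridor mid-migration, applies the road-avoidance term
`exp(β_road(decay − 1))` (β_road = 2.5, α = 10 km) to suitability, and
scores one community on the corridor beyond the crossing (expected
negative d) and one on the branch detour (expected positive d), with 10-km
buffers so the two remain distinct on the 100-km testbed.

## Problem sizes and defaults

Validation experiments run at 100×100 cells with 30 simulated individuals
(scenario recovery, map validation), 10,000 used / 200,000 available points
and ten replicates (decay-α recovery), n = 50,000 (coefficient recovery)
and 200 replicates at n = 2,000 (interval coverage), sizes at which each
experiment's statistical power comfortably exceeds its decision threshold
on a single CPU. The bundled demo pipeline uses a 60×60 km landscape with
8 animals. The availability ratio (20), stretch bounds (1–1,000),
8-neighbour connectivity, 20-km buffers, 10 folds and 500 bootstrap draws
are the method's standard settings and the package defaults.

## Known limitations

* The NSD rule needs a genuine plateau; nomadic or dispersal-like tracks
  are rejected rather than force-fitted.
* The Laplace GLMM uses independent (not correlated) random intercepts and
  a two-parameter variance search; it is not a general mixed-model engine.
* Scenario ranking cannot reliably separate adjacent negative transforms
  (above).
* The stretch is computed per surface; comparing absolute resistance
  values across surfaces is meaningless by construction — only within-map
  relative structure and cross-scenario rankings are interpretable.
* All geometry is planar km; reprojection is out of scope and a CRS tag is
  carried opaquely.
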