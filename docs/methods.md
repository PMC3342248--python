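# Methods

This note documents the statistical models behind `standforge`, the
defaults and why they were chosen, what the synthetic-stand generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Biomass estimation

**Tree allometry.** Each stem's component biomass (bole, branch, foliage,
or a whole-tree equation where components are not modelled separately) is
predicted from dbh on the equation's native scale — `log10(m) = c0 +
c1·log10(d)`, `ln(m) = c0 + c1·ln(d)`, or `m = c0·d^c1` — and
back-transformed **without** a smearing correction.  The lognormal
correction enters only through the SD: a log-scale standard error of
estimate `s` in base `b` maps to an arithmetic per-tree SD of
`m̂·sqrt(exp((s·ln b)²) − 1)`, the SD of a lognormal whose arithmetic mean
is `m̂`.  Keeping the point estimate as the naive back-transform and
putting the lognormal identity only in the SD mirrors the field convention
of reporting equation-driven uncertainty separately from the estimate.

Species or diameter classes outside any dissected equation resolve through
substitution rules: a proxy species for the component above a dbh
threshold, and/or a cap diameter — branch and foliage biomass of very
large firs and Douglas-firs are frozen at the value for the largest
dissected tree (110 cm and 162 cm respectively in the shipped rules)
because extrapolating crown allometry beyond the data inflates large-tree
biomass unrealistically.

The shipped `data/equations.csv` is a **demonstration registry**: its
coefficients are plausible for Sierra Nevada conifers (a 50 cm white fir
evaluates to ≈1.2 Mg, a 150 cm sugar pine to ≈16 Mg) but are not a
published compendium.  Real analyses must supply their own registry; the
file format (CSV mirroring the registry schema) is the supported interface.

**SD aggregation.** Per-species SD is the arithmetic *sum* of per-tree
SDs, and the plot SD the sum of species SDs — allometric error is treated
as perfectly correlated across trees sharing an equation.  This is the
conservative choice (independent errors would shrink as 1/√n and vanish on
30,000 stems) and matches how published plot tables sum their SD columns.

**Snags.** Bole volume is a frustum of a cone from dbh, top diameter and
height, `V = πh/3 (R² + Rr + r²)`; mass is volume times a wood density
specific to species group and decay class 1–5 (densities non-increasing
with decay).  The shipped density table is again a demonstration set.

**Shrubs.** Demography subplots give per-species stem and biomass
densities per m² of cover; multiplying by total mapped patch cover and
dividing by plot area gives stems/ha and Mg/ha.  Species without subplots
use documented proxies, including a half-scale proxy.

**Downed wood.** The planar-intercept identity `V/A = π² Σdᵢ²/(8L)` (dᵢ
intercept diameter in m, L transect length) is applied per transect,
piecewise with each piece's decay-class density; the plot value is the
mean over transects and the reported SD the between-transect spread.  The
identity is design-unbiased for volume per area under random transect
placement, which the test suite verifies by Monte Carlo against a
simulated piece field of known volume density.

**Fine fuels.** Per timelag class (1-h, 10-h, 100-h), mass per area is
`(π²/8)·n·QMD²·SG·1000·c_angle·c_slope / L_class` — exactly the intercept
identity applied to `n` pieces of constant quadratic-mean diameter, times
specific gravity and the lean/slope corrections.  Class QMDs and specific
gravities live in `data/fuel_coefficients.toml`.

**Litter and duff.** Mass = mean depth × bulk density.  Default bulk
densities (litter 125.2 kg/m³, duff 200.1 kg/m³) are calibrated so typical
Sierra mixed-conifer depths (≈1 cm litter, ≈1.2 cm duff) yield loads near
13 and 24 Mg/ha.

## Scaling fits

Stems are binned into 5 cm diameter classes, the first class [1, 5) cm;
bin "radius" is half the class-midpoint diameter.  Interior empty bins are
kept at count 0; no zero tail is appended past the largest occupied bin
(an unbounded zero tail would deflate r² arbitrarily).

The metabolic-scaling forms fix their exponents (`Δn = c·r⁻²`,
`M_bin = c·r^(2/3)`) and estimate only `c`, by closed-form least squares
on the untransformed bin values: `c = Σ(yᵢxᵢ)/Σxᵢ²` with `x = r^e`.
Fitting on the arithmetic scale is deliberate — there the residual
variance is dominated by the large-diameter bins, which is precisely where
the scaling prediction succeeds or fails, and it is the only scale on
which a flat biomass profile honestly produces r² = 0.  A `log_scale`
flag exposes the geometric-mean alternative for sensitivity analysis.

The negative-exponential alternative fits a density `a·e^(−b·d)` whose
**bin integral** `a/b·(e^(−b·lo) − e^(−b·hi))` is least-squares matched to
the counts.  Fitting the integral rather than the center-evaluated density
matters because the first bin is 4 cm wide while the rest are 5 cm; the
center approximation biases the recovered rate by ~15%, the integral form
recovers it to well under 5% at n = 50,000 (verified in the tests).
Reported r² is `1 − SSres/SStot` on untransformed values, floored at 0.

## Spatial statistics

**Estimators.** `K̂(r) = |A|/(n(n−1)) ΣΣ_{i≠j} w_ij⁻¹ 1(d_ij ≤ r)` with
the isotropic edge correction: `w_ij` is the fraction of the circle of
radius `d_ij` centered on point i that lies inside the rectangle, computed
in closed form (sum of the arcs cut off by each near edge minus the
double-counted corner sectors, `Σ 2·acos(dₑ/t) − Σ max(0, acosₑ + acos_f −
π/2)`), valid for r below half the shorter window side.  L is reported
centered, `L(r) − r`, so positive values read as clustering/attraction.
The default grid is 0–80 m in 0.25 m steps, with a warning beyond one
quarter of the shorter window dimension.

The bivariate `K̂₁₂` uses a symmetrized pair weight — the mean of the two
directed contributions `(w_i⁻¹ + w_j⁻¹)/2` — so the type-1-centric and
type-2-centric estimates are identical by construction (each directed
estimator is asymptotically unbiased, hence so is their average).

Below ~1 m the centered L of a sparse pattern carries a deterministic
negative bias (`≈ −r·P(K̂ = 0)`) from the square-root transform; this is a
property of the transform, not of the estimator, and the CSR calibration
test therefore checks near-zero mean from 1 m outward.

**Null models.** CSR is a binomial process — n points uniform, n fixed at
the observed count.  Population independence keeps each subpattern
internally rigid and applies an *independent* uniform toroidal shift to
each before recomputing the bivariate statistic; shifting both patterns is
distributionally equivalent to a single relative shift and is the default
(a single-shift variant would behave identically).  Toroidal shifts
preserve point counts and all toroidal-metric pairwise distances exactly.

**Inference.** Envelopes return the full simulated curve set (pointwise
quantiles are derived on demand, and curves beyond the formal test range
support exploratory reading).  The Loosmore–Ford statistic integrates the
squared deviation of each curve from the mean of *all other* curves over
[r_min, r_max] (default 0–9 m, the neighborhood scale for these forests)
with Δr the grid step; the p-value is the rank of the observed deviation,
`(1 + #{u_sim ≥ u_obs})/(n_sim + 1)`, ties counted as extreme
(conservative).  L̂ is the default summary; K̂ is available via a flag.
Families of tests use the Bonferroni threshold α/m reported to 3 decimals.

**Correlogram.** Transect-level debris volumes are paired by inter-midpoint
distance class; within a class the Pearson correlation is computed with
both orderings of every unordered pair (symmetric, Mantel-correlogram
style) and tested by permuting values across transects (999 permutations,
two-sided rank p).  Zero-variance or empty classes are flagged not
estimable rather than returning a number.

## The synthetic-stand generator

The generator's defaults emulate the structure of an old-growth Sierra
Nevada mixed-conifer plot so that the downstream analyses have realistic
targets: ≈1,350 live stems/ha dominated by white fir; ≈19 large
(≥100 cm) trees/ha; small trees aggregated below ~20 m (Thomas process,
parent intensity 0.020/m², mean 9 offspring, 4 m dispersal); large trees
near-random with a 2 m hard core (sequential thinning of a Poisson
proposal); small trees thinned with probability 0.8 within 10 m of a
large tree, producing bivariate segregation below 10 m; a
negative-exponential dbh distribution with rate 0.104/cm (so ~39% of
stems are ≥10 cm) and a rotated-sigmoid alternative (exponential +
mid-diameter Gaussian hump mixture — a stand-in parametric form, since no
canonical family exists for that shape); snags at 19.9% of the ≥10 cm
live count; ~15% shrub cover from a Boolean disc model; and a debris
field of straight constant-diameter segments (0.025 pieces/m², mean
length 8 m, 1.5% of pieces ≥100 cm) sampled by 112 twenty-meter
transects with exact segment–line crossing geometry, so intercept
diameters equal piece diameters with no discretization.

All randomness flows from one seed through NumPy's PCG64; each layer draws
from its own spawned child stream, so layers are independently
regenerable and the full dataset is bit-reproducible (writers emit
shortest-round-trip float strings).

What the generator does **not** emulate: topographic and edaphic
heterogeneity (intensity is spatially homogeneous), correlations between
tree size and location beyond the large/small dichotomy, snag spatial
clustering around mortality centers, tapering or curved debris pieces,
fine-fuel spatial structure (tallies are i.i.d. Poisson per transect), and
temporal dynamics of any kind.  Passing tests therefore demonstrate that
the estimators and tests behave correctly on data with the assumed
structure — not that real census data satisfy those assumptions.

## Pipeline and reproducibility

The report runner regenerates every table from the raw layers on each run
(no cached intermediates), derives its two RNG streams (spatial, 
correlogram) from the config seed, and writes round-half-even values at
the precision of the corresponding published table (1 d.p. percentages
and densities, 3 d.p. Mg/ha).  A failure in any stage removes partial
outputs and raises a stage-named error.  The run log records seed, config
hash (excluding the output path), and package versions.  Test problem
sizes are scaled to desk hardware: the shared fixture stand is 2.56 ha
(~3,300 stems), Monte-Carlo calibrations use 100×100 m windows with
50–160 points, 99 simulations per test and 200–500 replicates.

## Known limitations and discrepancies

* Published tallies for the plot this workflow models contain two internal
  inconsistencies the package resolves in favor of table arithmetic: the
  large-snag share of snag *count* computes to 7.8% (210/2,697) although
  the source text states 12.4%, and the printed shrub-biomass total
  (4.103 Mg/ha) exceeds the sum of its printed rows (4.073 Mg/ha).  The
  pipeline always reports sums of its own rows.
* The isotropic correction is the only edge correction offered; r beyond
  half the shorter window side is unsupported.
* SD propagation ignores sampling covariance between pools; only
  allometric (trees) and between-transect (debris, fuels) spread is
  reported.
* The demonstration equation registry, density table and fuel
  coefficients are placeholders with realistic magnitudes, not published
  values.
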