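# Methods

`ecoca` simulates regional land-use change on a square lattice of 100 m
cells carrying four classes — cultivated land, ecological land (forest,
grassland, wetland), construction land and other land — under three policy
scenarios. The model couples a **macro controller**, which fixes how much
area each class should reach, with a **micro cellular automaton (CA)**,
which decides *where* that change happens. A synthetic-landscape generator
with known ground truth makes every stage testable without external raster
data.

## Macro controller

The inter-class transition areas between two observed epochs are
cross-tabulated into a 4×4 matrix T (km²); row-normalizing gives the Markov
state-transition probability matrix P. Class areas are projected as
X_{t+k} = X_t P^k, one step per five-year monitoring interval (the natural-
development scenario projects three steps beyond the later calibration
epoch). Two algebraic identities are enforced exactly and tested: the row
and column sums of T are the two epochs' area tables, and one projection
step with the estimated P reproduces the later epoch's areas.

Goal-driven scenarios replace the Markov projection with planning caps: a
construction-increment ceiling and a cultivated-decline percentage. The
residual area is split between ecological and other land in their
base-epoch ratio. Both caps are expressed as fractions of the total
landscape area (construction +1.8553 %, cultivated −1.4005 % under object
orientation, −2.0080 % under ecosystem priority), mirroring the structure of
the study region's planning figures: under ecosystem priority the cultivated
decline exceeds the construction gain, so ecological land is planned to
grow; under object orientation it is not, and ecological land shrinks
slightly.

Iteration stops per class once its cell count enters the closed band
[target − N, target + N]. N defaults to 1 % of the class target (at least
one cell); the band is a model input, not an estimate.

## Conversion suitability

Conversion of a cell to target class m ∈ {cultivated, ecological,
construction} is modeled by a binary logistic regression on seven drivers —
distances to the nearest town, highway and river, elevation, slope, per-
capita GDP and population density — each min–max normalized to [0, 1].
"Other" land has no suitability model (the calibration protocol defines only
the three conversion outcomes) and therefore only loses cells during
simulation; its area declines in every scenario, consistent with the
region's accounting.

Observations are the *convertible* cells: cells not already in the target
class at the start epoch, excluding cells under a hard constraint mask.
Masked cells cannot convert by construction, and the steep-slope mask is a
deterministic function of the slope driver, so including them would bias the
slope coefficient toward zero; excluding them makes the fit a correctly
specified model of the cells the CA can actually move. Fits are maximum
likelihood (statsmodels `Logit`); perfect separation is reported as an
error.

The three fitted probability surfaces are made coherent per cell by Theil
(ratio) normalization, P′(i_j) = P(i_j) / Σ_k P(i_k), which preserves the
per-cell argmax. Ties break to the lowest class code.

## CA engine

Each iteration composes, per candidate cell,

    P_T = P′ (suitability) × Ω (neighborhood) × con (constraint) × R (stochastic)

* Ω is the share of the 3×3 Moore neighborhood (center excluded, edge cells
  use their in-bounds neighbors) already in the candidate class, so growth
  is frontier-driven and compact.
* con ∈ [0, 1] encodes the scenario constraints, with a separate
  construction-only component for the steep-slope rule:
  natural development protects basic farmland; object orientation protects
  basic farmland and water; ecosystem priority protects the whole core set
  (basic farmland, water, first-level water sources, nature reserves, scenic
  and geological parks), blocks construction above 25° slope, and prohibits
  any conversion out of ecological land.
* R = 1 + (−ln γ)^α with one fresh γ ~ U(0, 1) per cell per iteration, the
  stochastic-disturbance term conventional in land-use CA models.
  α ∈ {1..10} scales the disturbance; the default is 1 (the least
  disruptive setting — larger α flattens the suitability signal because the
  boost's tail dominates).

**Normalization and threshold.** The deterministic product P′ × Ω × con is
min–max normalized to [0, 1] over the iteration's candidate cells; R then
multiplies the normalized score, and cells at or above the threshold
(default 0.8) become eligible. An alternative composition — normalizing
*after* multiplying by R — was implemented first and rejected: with a
heavy-tailed R inside the normalizer, the maximum is an extreme draw and the
expected number of threshold-passers scales like n^0.2 (a handful of cells
per iteration on a 360 000-cell lattice), so no macro demand can ever be
met. The adopted composition keeps the threshold meaningful: a cell with
normalized score v passes with probability exp(−(θ/v − 1)^{1/α}) for v < θ,
a smooth, suitability-ordered gradient. A `threshold_direction='lt'` option
reproduces the literal below-threshold conversion rule for comparison.

**Allocation.** Two phases per iteration. Phase A develops construction:
eligible non-construction cells convert highest-score first, capped by the
remaining construction demand; construction is absorbing (all scenario
targets are non-decreasing in construction and the reallocation rule's
target set excludes it). Phase B reallocates remaining convertible cells to
the better of cultivated/ecological where that class still needs cells.
A class accepts cells only up to its exact target, and sheds them only while
above it — every conversion strictly reduces the total absolute gap, so
convergence into the stopping bands is monotone (a met-but-below-target
class may still top up; freezing it entirely can deadlock a surplus class).
Ties in the priority order break by row-major cell index, so a run is
bit-reproducible from its seed. Conservation of the total cell count is
asserted every iteration.

## Landscape evaluation

Class-level pattern indices follow the Fragstats conventions: 8-neighbor
patch connectivity, perimeters in cell-edge units (edges to other classes,
nodata or the boundary), 4-neighbor single-count adjacencies.

* LPI = 100 · max aᵢ / A
* COHESION = [1 − Σpᵢ / Σ(pᵢ√aᵢ)] · [1 − 1/√A]⁻¹ · 100
* SPLIT = A² / Σaᵢ²
* AI = 100 · g / g_max with the combinatorial bound g_max(a) = 2n(n−1) + f(m),
  n = ⌊√a⌋, m = a − n²; f = 0, 2m−1 or 2m−2 as m = 0, ≤ n or > n.
  A single-cell class has g_max = 0 and is reported as AI = 100 with a
  warning.

All four are verified against independent plain-Python flood-fill/edge-scan
oracles to 1e-9 on random grids. The evaluator also reports per-class area
change (km² and %), cellwise overlay accuracy, and key-ecological-land loss
by security level (masked cells ecological at the base epoch and not at the
end epoch). Published area tables are accepted even when their printed
columns miss the landscape total by a fraction of a percent (it happens);
mismatches above 1 % are rejected.

## Synthetic landscape generator

The generator emulates the statistical structure the calibration assumes,
at the feature density of a large administrative region rather than a small
tile:

* **Drivers.** Distances are exact Euclidean distance transforms from seeded
  point features (100 towns on the default 600×600 lattice) and random-walk
  polylines (20 highways, 14 rivers). The DEM is a sum of Gaussian hills
  plus short-range smoothed noise, giving a realistic hypsometric spread;
  slope is its gradient magnitude. Socio-economic surfaces are power-2 IDW
  interpolations of point values drawn from a U-shaped Beta(0.4, 0.4)
  (polarized county indicators). All layers are min–max normalized.
  These choices are identifiability-driven: low feature density and purely
  smoothed-noise terrain produce near-collinear, low-variance covariates on
  which no sample size attainable on the lattice can pin the regression
  coefficients to the ±15 % recovery tolerance the test suite demands; at
  the default density every coefficient's tolerance band is ≥ 2 standard
  errors of the census fit.
* **Initial map.** Class affinity scores (construction near towns,
  ecological on high or steep terrain, cultivated on flat land) plus
  smoothed noise; greedy quota allocation makes realized shares match the
  requested shares (default 25/56/18/1 %) exactly up to rounding.
* **Truth process.** A convertible cell converts to class m with probability
  σ(β*₀ₘ + β*ₘ·x); competing classes occupy disjoint sub-intervals of one
  uniform draw, so each marginal is exactly logistic and the calibration fit
  is correctly specified. The per-class "transition intensity" is the
  intercept. Default coefficients have slope magnitudes ≥ 1.2 (no near-zero
  entries, which could not be powered at this n) and intercepts chosen so
  the realized epoch-to-epoch trend matches the study system: construction
  expanding strongly (≈ +35 %), ecological and cultivated land losing on
  net. Masked cells never convert; realized transition counts are recorded
  exactly.
* **Masks.** Basic farmland ⊂ cultivated, water ⊂ ecological∪other near
  rivers, core areas ⊂ ecological, steep slope = top slope quantile, and
  disjoint low/high-security key-ecological-land subsets of ecological
  cells.

What the generator does **not** emulate: real geography (actual road
networks, hydrology, urban form), spatially autocorrelated regression
residuals, multi-date socio-economic trajectories, or class-dependent
conversion propensity beyond the driver signal. Passing tests therefore
demonstrate the machinery is correct and well-calibrated on data satisfying
the model's own assumptions — not that the fitted coefficients or simulated
maps would be accurate for any particular real region.

## Numerical choices and degenerate inputs

* Min–max normalization rejects constant layers (undefined range) and
  propagates NaN.
* Empty transition-matrix rows (a class absent at t0) get an identity row
  and are flagged rather than NaN-filled.
* All-zero suitability cells are assigned the uniform distribution and
  flagged during Theil normalization.
* Candidate scores that are all zero in an iteration produce no conversions;
  an all-equal positive score maps to 1.
* Areas are computed at full precision and rounded only for display.
* Integer cell targets are rounded per class with the largest class
  absorbing the rounding drift, so targets conserve the lattice total
  exactly.
* One top-level seed fans out to per-stage seeds via a CRC-based hash of the
  stage name; identical configuration + seed reproduces every artifact
  bit-for-bit.

## Problem sizes

Default study conditions: a 600×600 lattice (360 000 cells, 3 600 km² at
100 m resolution), census calibration (~310 000 design rows, ~150–250 k
per-class convertible observations), three scenario simulations of a few
dozen iterations each. A full end-to-end run (generate, calibrate, simulate
all three scenarios, evaluate) completes in well under a minute on one CPU.
Unit and property tests run on 30×30–120×120 lattices.

## Known limitations

* The reallocation phase considers only the best non-construction target
  per cell per iteration; a cell whose best class is demand-saturated waits
  for the next iteration instead of falling back to its second choice.
* Markov projection is time-homogeneous; planning caps are linear in the
  base areas.
* The overlay-accuracy hindcast validates area allocation, not patch
  geometry; two maps with identical class areas and different shapes can
  score equally.
* GeoTIFF I/O is not implemented; the on-disk dialect is ESRI ASCII Grid.
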