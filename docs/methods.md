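# Methods

## Effect model

The package upscales meta-analysis effect sizes for earthworm presence to
gridded crop production. The central object is the per-cell, per-crop
fractional yield effect

    E_ik = c_k · p_i · t_i · n_ik · a_i · E0

where `E0 = 0.233` is the mean fractional increase in aboveground biomass
with earthworms present, and the remaining factors are dimensionless
multipliers for crop type (c), soil-pH class (p), soil-texture class (t),
crop-specific fertilizer-N class (n) and earthworm abundance (a). The
factors are assumed independent (purely multiplicative); no interaction
terms are modelled, mirroring the structure of the evidence base, which does
not resolve interactions.

### Categorical coefficients

For each factor, the effect-size table lists per-category percent effects
e_j with sample sizes n_j. The sample-size-weighted mean
ē = Σ n_j e_j / Σ n_j is the factor's reference level and each category's
multiplier is c_j = e_j / ē. Two consequences are used as invariants in the
tests: the n-weighted mean of the multipliers is exactly 1, and a factor
whose categories all share one effect yields unit multipliers everywhere.

Coefficient arithmetic always uses the unrounded weighted mean; printed
2-decimal reference values appear only in tests, with ±0.005 (means) and
±0.001 (coefficients) tolerances.

The shipped table includes a grass category of the crop-type factor that has
no corresponding crop data layer. It is flagged `applies_to_map=False`:
it contributes to the weighted mean (the reference level reflects the full
evidence base) but receives no multiplier. Effect signs in the shipped
transcription are all positive; this is forced by the positivity of the
published per-category multipliers.

### Abundance

Abundance enters continuously as a power law through the origin,
`a(x) = k·x^b` with shipped defaults `k = 0.1032`, `b = 0.409`
(x in individuals m⁻²). The continuous form is deliberately conservative:
most cells in real global abundance maps fall below the 100 ind. m⁻²
threshold of the lowest categorical density class, and the power law lets a
cell with a handful of individuals have a near-zero effect rather than the
full low-class effect. `a(x)` is strictly increasing with `a(0) = 0`, so E
is monotone in abundance and zero-abundance cells contribute nothing.

`fit_abundance_power` fits (k, b) by ordinary least squares on log–log
transformed points. The underlying calibration data for the shipped
defaults are not distributed with the evidence table, so the fit is provided
generically (it recovers generating parameters exactly on noiseless data and
is cross-checked against a brute-force grid search in the tests) while the
shipped (0.1032, 0.409) remain the authoritative defaults regardless of any
refit.

## Layer preparation

* **Depth aggregation.** Soil property stacks follow the SoilGrids standard
  intervals 0–5, 5–15, 15–30, 30–60, 60–100 cm and are collapsed by
  thickness-weighted averaging, weights (5, 10, 15, 30, 40)/100. Whether
  thickness or equal weighting is the "right" reading of a 0–100 cm average
  is genuinely open; thickness weighting is the default and
  `weighted=False` gives equal weights. Cells with a partial stack
  renormalize weights over available layers (consistent with the
  exclude-missing philosophy used in upscaling); `renormalize=False` masks
  any incomplete cell instead.
* **Classification.** pH: low < 5.6, 5.6 ≤ medium ≤ 7.0, high > 7.0 — both
  endpoints belong to the medium class, matching the interval notation of
  the source table with strict inequalities on the outer classes. Texture:
  sandy > 70 % sand, clayey > 35 % clay, loamy otherwise; the classes are
  exclusive because sand + clay ≤ 100 is enforced. N rate: low ≤ 30
  kg N ha⁻¹ yr⁻¹ (inclusive), high above. Classification is a pure per-cell
  map and propagates masks.
* **Upscaling.** Block-averaging excludes missing fine cells; an all-missing
  block becomes missing. Non-divisible shapes are padded with missing cells
  on the south/east edges (common raster-aggregation behaviour) rather than
  erroring.
* **Geometry.** Cell-center registration, north-up rows, lon-lat axes,
  0-based indexing. These conventions are fixed here because the consumed
  data products leave them implicit. Rasters are exchanged as plain-text
  ESRI ASCII grids whose nodata value maps bit-exactly to the missing mask;
  category rasters are integer-coded with a sidecar CSV legend.

## Counterfactual conventions

The phrase "yields with and without earthworm impact" admits two readings,
and both are implemented:

* `counterfactual_division` (default): observed yields already contain the
  earthworm benefit, so `y_without = y_obs / (1 + E)` and the attributable
  share of observed production is exactly `E / (1 + E) ∈ [0, 1)`. This
  matches reporting contributions as a percent of *total* (current)
  production and is the convention under which the synthetic known-truth
  check is an algebraic identity.
* `forward_multiplication`: observed yields are earthworm-free and
  `y_with = y_obs · (1 + E)`.

The chosen mode is recorded in every run manifest. Relative contributions
always use observed (with-earthworm) production as denominator. Cells
without earthworm data are omitted from both numerator and denominator by
default — they never enter the model — but `include_all_production=True`
puts all observed production in the denominator, since either reading of
"% of total" is defensible.

Negative E cannot arise from the shipped coefficients; if user-supplied
coefficients produce one, E is clamped at zero and a warning logged.

## Aggregation

Per-crop effect maps are masked to each crop's production area (harvested
area strictly positive). The cross-crop mean effect map weights each crop's
E by its harvested area per cell. Regional totals sum attributable and
observed production over a region-identifier raster (region assignment is
raster-based; rasterizing country polygons is out of scope) for eight
continental-scale agricultural regions — Sub-Saharan Africa, Northern
Africa and Western Asia, Central and Southern Asia, Eastern and
South-Eastern Asia, Latin America and the Caribbean, Oceania (including
Australia/New Zealand), Europe, and Northern America. The global row is the
sum of the identical regional summands, so conservation is exact. Cells
carrying production but no region id are tallied under `unassigned` and
logged.

## Synthetic worlds

The generator emulates only the statistical features the pipeline is
sensitive to:

* abundance log-normal with location 3.4 and scale 1.2 (median ≈ 30
  ind. m⁻², well over half of cells below 100 ind. m⁻², a long right tail),
  with a configurable fraction (default 10 %) of cells masked as unsampled;
* spatially smooth pH and texture fields built by Gaussian-filtering white
  noise (kernel σ = 4 cells, wrap boundary) — real soil maps have spatial
  structure but no particular form is assumed; pH is clipped to 3.8–9.0 and
  sand + clay rescaled to ≤ 95 % so every class occurs;
* per-crop N rates as a low/high gamma mixture (40 % low at mean 12, 60 %
  high at mean 120 kg N ha⁻¹ yr⁻¹) so both fertilization classes are
  exercised in every default world;
* four cereals (wheat, rice, maize, barley) and two legumes (soybean, dry
  bean) — a reduced-cardinality stand-in for the full crop lists — with
  log-normal yields (median 3 t ha⁻¹) and areas (median 500 ha, 10 % of
  cells zero);
* eight contiguous column-band regions.

What the generator does **not** emulate: realistic spatial covariance
between drivers (abundance is independent of pH and texture), coastlines
and land masks, latitude-dependent cell areas, or the sampling bias of real
abundance maps. Passing tests therefore demonstrate correctness of the
*computation* — coefficient arithmetic, masking, counterfactual algebra,
aggregation — not fidelity of any real-world estimate; published global
numbers additionally depend on the external global data products, which are
out of scope here.

In known-truth mode the drawn yields are reinterpreted as earthworm-free
baselines, E is evaluated on the generated drivers, observed yields are set
to `baseline · (1 + E)`, and the exact attributable production
`baseline · E · area` is tabulated per region. Running the pipeline in
division mode on the constructed observed yields recovers this table to
floating-point accuracy (`y_obs / (1 + E) = baseline` is an identity); this
is the package's primary end-to-end check, run at 100×100 cells with six
crops in the acceptance script and tests — small enough to complete in
seconds, large enough that every category, mask path and region is
exercised.

## Numerical notes

* All randomness flows from one `numpy.random.default_rng(seed)`; fixed
  seeds give bit-identical worlds on a given numpy generator algorithm.
* Regional/global conservation is exact only when sums are accumulated in
  the same order; the global row is built from the identical regional
  summands sequentially.
* Power-fit degeneracies: fewer than two points, or any nonpositive
  abundance/multiplier, are errors; constant data legitimately returns
  exponent 0.
* The unit-multiplier abundance `x* = (1/k)^(1/b) ≈ 258 ind. m⁻²` is the
  point where the continuous abundance term neither damps nor amplifies the
  baseline effect.
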