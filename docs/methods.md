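# Methods

## Ranking model

The prioritizer is a greedy cell-removal algorithm over a stack of
co-registered feature layers.  Writing `Q_j` for feature *j*'s total over
valid cells, `p_ij = q_ij / Q_j` and `R_j` for its remaining proportion,
the additive benefit function assigns cell *i* the marginal loss
`δ_i = Σ_j w_j [R_j^z − (R_j − p_ij)^z]`; the cell with the smallest
`δ_i` is removed, the affected `R_j` are updated, and the process repeats
until the landscape is empty.  A cell's rank is its removal step divided
by the number of valid cells, so the ranks over the landscape are exactly
the set `{k/n}` — the rank histogram is uniform by construction, which
the evaluation module exploits as its null hypothesis.

Choices worth stating:

* **Exponent `z`.** Default 0.25.  Any concave benefit (`z < 1`)
  produces the qualitative behaviour the analyses rely on — emphasis on
  feature-rich cells and long retention of range-restricted features;
  0.25 follows the convention of the widely used reference software.
  `z` is a config knob and is recorded with every pipeline run.
* **No cost or connectivity terms.**  Cell cost is identically 1; no
  boundary-length penalty.  The method is a pure representation ranking.
* **Exactness vs speed.**  `batch_size = 1` re-evaluates every remaining
  cell after each removal and is the exact greedy (it is tested for
  equality against an independent brute-force implementation on
  instances up to 100 cells × 10 features).  Larger batches remove the
  `batch_size` cheapest cells per evaluation; this is an approximation
  whose agreement with the exact order is checked only statistically
  (rank correlation) in the tests.
* **Ties.**  Broken by stable row-major index by default (reproducible
  and convention-free); a seeded random tie-break is available for
  sensitivity checks.
* **Numerics.**  `R_j − p_ij` is clamped to 0 when it is negative by
  less than 1e−12 (float drift near full removal); a larger violation
  raises, because it indicates an inconsistent state rather than
  round-off.
* **Mask-constrained ranking** removes every unmasked cell before any
  masked cell, each stratum in ABF order with the `R_j` carried across
  the strata, so masked reserves occupy the top ranks and the best
  expansion cells appear directly below them.  A `flatten_mask_rank`
  flag additionally sets all masked ranks to exactly 1.0 for map output;
  it breaks the permutation property and is never used in the analyses.

## Curves, AUC and surrogacy

Performance curves are evaluated at the exact removal steps (a staircase
with `n + 1` points), so no interpolation error enters; a uniform-grid
resampling exists only for plotting and CSV export.  AUCs use the
trapezoid rule, under which the mean of per-feature AUCs equals the AUC
of the mean curve, so it is immaterial whether averaging happens before
or after integration.  Mean curves average features, never cells, and
never apply the prioritization weights; built-up layers are excluded
from every mean and reported separately.

Surrogacy runs give each surrogate feature weight 1 and each target
weight 0 (targets are present in the stack and get curves, but cannot
influence `δ_i`); built-up layers keep their cumulative −1 in every run,
including the random baselines.  The random baseline draws one iid
uniform(0,1) layer per run as the sole positively weighted feature —
ranking on a single layer is a random permutation, which is the "area
only" null the SAI needs — and averages the targets' mean curve over the
runs (100 by default; the pipeline's desk-scale default is 20).  The
number of noise layers per run is configurable but one is the default.
`SAI = (S − R)/(O − R)` raises a degenerate-baseline error when
`O = R` rather than returning a number.

## Protected-area evaluation

Rank values inside the reserve mask are binned into 10 equal-width bins
on (0, 1] (half-open on the left, so rank 1.0 lands in the top bin) and
tested against uniformity with Pearson's χ² (df = n_bins − 1 = 9 at the
default).  The bin count is configurable; 10 is the default because it
matches the degrees of freedom reported in the kind of national gap
analysis this package reproduces.  p-values below 2.2e−16 are reported
textually as a bound, exactly in JSON.  Representation is
`Σ_{i∈PA} q_ij / Q_j` per feature, with the reserve network's areal
fraction as the random expectation; group summaries use median and
quartiles, and no multiple-testing correction is applied anywhere.
Range sizes are the plain sum of suitabilities for species-type features
and occupied area in km² (fractional cover × cell area) for
habitat-type features.

## Synthetic landscapes

The generator provides the statistical structure the analyses assume,
not geographic realism.  All fields derive from seeded white noise
smoothed with a Gaussian kernel (`smoothness` = autocorrelation length
in cells, default 2) and every generator is a pure function of its
arguments and seed.

* **Region**: a rectangle, or a single connected blob grown greedily
  along a smoothed field to the requested valid fraction.
* **Habitat mosaic**: per-class smoothed fields at `subgrid_factor`×
  (default 10×) the analysis resolution; each fine cell takes the argmax
  class, yielding contiguous patches that cover the region.  Built-up
  classes are down-weighted (×0.8) before the argmax so they form the
  small clustered patches real artificial surfaces make (a few percent
  of the landscape at the defaults).  Fractional aggregation of the
  mosaic to the analysis grid is exact on integer counts.
* **Species**: each layer is a Gaussian occupancy kernel modulated by a
  noise texture and normalised to a target total; targets are log-spaced
  so the largest/smallest ratio equals `range_size_spread` (default 10).
  Each species is tied to one habitat class — rarest classes to the most
  range-restricted species — its kernel centre is sampled from that
  class's cover, and a low habitat-tracking floor (`0.15 · cover ·
  texture`) extends suitability over the whole region the way continuous
  model output does.  With probability `hotspot_overlap ·
  (range-restriction rank)` the centre is drawn near one of ≤ 3 shared
  hotspot locations, so small-range features co-occur in richness
  hotspots; this is the mechanism behind the negative AUC–range-size
  trend the tests assert.
* **Protected areas**: `round(coverage · n)` cells sampled without
  replacement with weight `exp(bias · rank)` (Gumbel top-k), giving a
  single dial from uniformly random (`bias = 0`) to strongly
  value-seeking placement.

Default study conditions: 30 × 30 cells of 1 km², 12 species, 8 habitat
classes plus 2 built-up classes, 23% reserve coverage, value bias 2.
These are desk-scale analogues chosen so every analysis runs in seconds;
the spatial covariance parameters are conventions, not estimates of any
real layer set.  What the generator does **not** emulate: projection and
coastline geometry, class-imbalance extremes, spatially structured
observation error in the suitability models, and the circularity that
arises when habitat layers are predictors of the species models (the
habitat-linked species here make that coupling explicit and
controllable).  Passing tests therefore demonstrate correctness of the
algorithms and the stated qualitative behaviours, not quantitative
transferability to any particular real landscape.

## Raster handling

One grid convention everywhere: row-major, row 0 at the north edge,
0-based indexing, origin at the outer corner of the top-left cell,
half-open extents.  ESRI ASCII grids round-trip losslessly (values are
written with shortest-round-trip precision; nodata sentinel −9999);
GeoTIFF goes through tifffile with the standard ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags.  No CRS handling — layers are
assumed co-registered and stack assembly rejects any mismatch in shape,
cell size, origin or valid mask.  Fractional aggregation computes class
shares over the *valid* fine cells of each block, so region edges are
not deflated.  Resampling to a finer grid treats values as intensive
quantities (probabilities): bilinear interpolation at cell centres
(nearest-neighbour by flag) preserves a constant layer exactly and the
mean approximately; the relative change of the mean is logged on every
call.

## Pipeline and reproducibility

`run_pipeline` executes synth → prioritize → curves → surrogacy →
evaluate → expand from one `RunConfig`; the config's single `seed`
governs every stage (stage seeds are derived from it, and it overrides
the synthetic generator's own seed field).  Each run writes a resolved
config copy and a manifest with SHA-256 hashes of every artifact;
identical configs reproduce identical hashes.  Problem sizes in the test
suite and acceptance script (15–30 cells a side, 4–12 features,
10–100 random runs) were chosen so the full suite completes in well
under a minute per module while still exercising every code path at
non-trivial scale.

## Known limitations

* Only the additive benefit removal rule is implemented — no core-area
  zonation, target-based planning, condition or interaction layers.
* The batch approximation has no analytic error bound; use
  `batch_size = 1` when exactness matters (it is the default).
* Bilinear resampling near nodata edges fills from the nearest valid
  cell before interpolating, which slightly smears values across the
  region boundary.
* The SAI is undefined when the optimal and random baselines coincide;
  degenerate stacks (e.g. a single spatially uniform target) trigger an
  explicit error instead of a silent 0/0.
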