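# Methods

## Coordinate and raster model

All geometry is planar Cartesian in metres. Rasters use the image
convention (origin at the upper-left corner, row index increasing
downward); the centroid of cell `(r, c)` is at
`(origin_x + (c + 0.5)·cell_size, origin_y + (r + 0.5)·cell_size)`. Real
population grids are geographic, but the validation only needs areas and
point-in-polygon containment, and a planar frame makes both exact and
testable. Counts are real-valued persons per cell (dasymetric
disaggregation produces fractional persons); cells are square. Rasters are
stored as single-band float64 TIFF with the grid's origin, cell size,
reference year and dataset name in a JSON blob in the ImageDescription tag.
Nodata (NaN) cells are zero-filled on read with a logged count — how real
products' nodata should be treated is not observable from the validation
itself, and zero is the conservative choice for a count raster. Reading a
raster that lacks a reference year or dataset name requires the caller to
supply them; they are never guessed.

## Reference-year rule

`select_reference_year` implements
`Y_ref = Y − (k + Y mod k)` with `k = 5` (the vintage interval), i.e.
rounding the completion year down to the **second** closest map vintage, an
offset of 5–9 years. Rationale: very large dams take on the order of 8–9
years to build and resettlement happens gradually during construction, so
the map one vintage earlier than the closest is the last one that still
shows the pre-resettlement population. The `late` mode adds one more
interval (offset 10–14 years) for sensitivity analysis. `mod` is the
non-negative remainder. Results outside the configured valid vintage range
(default 1975–2010) raise a named error carrying the offending year; in
`predict_all` such records become logged skips rather than failures,
mirroring the uneven temporal coverage of real products.

## Inclusion filters

A reservoir enters the validation iff (defaults, all configurable):

- a resettlement figure exists (missing is `None`; a reported zero is kept —
  it is a legitimate census result, not missing data);
- reported surface area **strictly** greater than 1 km²;
- completion year ≥ 1980;
- implied density (resettled persons / reported area) **strictly** below
  1500 people/km² — the density threshold used to delineate urban areas, so
  the retained footprints are rural;
- neither manual exclusion flag (transboundary, pre-existing reservoir) set;
- country not in an optional exclusion list.

Strictness at the two numeric thresholds is a choice (the boundary cases
are measure-zero in practice); it is asserted in tests so a change would be
visible. The density criterion uses reported attributes only, because it
must be evaluable before any geometry work. Filters are idempotent and
order-independent; every rejection is audited with the full list of
violated criteria, and kept/rejected partition the input exactly.

## Zonal extraction

`zonal_population` refines the grid by an integer factor (default 10;
splitting each count evenly over factor² children — the mass-preserving
refinement) and sums the refined cells whose centroids the polygon covers.
Centroids on the boundary count as inside (a consistent, measure-zero
convention). The implementation only enumerates refined centroids within
the polygon's bounding box and evaluates containment with vectorised
prepared-geometry predicates; tests check it against an independent oracle
that materialises the full refined grid and tests every centroid. Partial
overlap with the grid is allowed; cells outside contribute zero. A factor
of 10 relative to the native resolution keeps the discretisation error of
the centroid rule well below the percent level for footprints larger than
a few native cells while bounding cost; it is configurable.

## Area-bias estimation and adjustment

Published reservoir polygons are usually digitised from satellite scenes
that may show a partly filled reservoir, so their geometric area falls
short of the reported maximum surface area. The mean shortfall fraction
`b` is estimated from matched (reported area, polygon area) pairs after two
drops: pairs with reported area ≤ 1 km², and pairs whose areas disagree by
a factor of more than `max_ratio` (default 5) in **either** direction — the
ratio test is symmetric because a direction is not specified by the
phenomenon. The default estimator is the aggregate (ratio-of-sums) form
`b = (Σ reported − Σ polygon) / Σ reported`, consistent with the bias
metric's structure; an unweighted per-pair mean is selectable by flag since
"mean shortfall" is ambiguous between the two (they coincide when all
reservoirs are the same size). The adjustment multiplies every raw zonal
sum by `1/(1−b)` uniformly (for `b = 0.188`, ×1.2315), which assumes the
population density in the missing rim equals the density inside the
polygon. The pipeline can either use a fixed `b` (default 0.188) or
estimate it from its own inputs.

## Accuracy metrics

`Bias` is `(Σ predicted − Σ reported)/Σ reported × 100%`, bounded below by
−100% and zero iff totals match. Being a ratio of sums, per-group biases
recombine exactly to the pooled bias — a property test guards this.
`sMAPE` is the mean over pairs of `|r − p|/(|r| + |p|)`, in [0, 1],
symmetric in its arguments and invariant to rescaling a pair; the mean runs
over exactly the n pairs, and a 0/0 pair contributes 0 (perfect
agreement; it can occur in synthetic data even though filtered real data
cannot produce it). No pair is weighted by population or area anywhere.
Stratified summaries group by dataset, reference year, income level and
country, with an optional inclusive year-range restriction (e.g. limiting
an income-level comparison to vintages 2000–2010 so temporal accuracy
trends do not confound it). The per-country mean bias across datasets is
unweighted and averages only the dataset cells a country actually has.

## Synthetic world

The generator's defaults define the study conditions:

- **Truth field**: 400 × 400 km at 1 km resolution; a uniform rural floor
  of 10 people/km² plus 400 settlement clusters, each holding a
  Poisson(2000) number of persons scattered with a 2 km isotropic Gaussian
  around a uniform centre (points clamped to the extent so no mass is
  lost). This yields ~2.4 M people at rural densities with realistic
  clumping.
- **Reservoirs**: 307 non-overlapping convex footprints, areas log-uniform
  on 1.5–400 km² (small reservoirs most common with a tail of large ones),
  completion years uniform on 1985–2015 so every reference year 1975–2005
  is exercised. Placement is rejection sampling, largest first, capped at
  10 000 attempts per polygon; an infeasibility (total area above 25% of
  the extent) is a named error. Reservoirs are sampled anywhere — the
  density filter downstream is what enforces rurality, exactly as in the
  real pipeline, rather than pre-censoring the sample.
- **Polygon shrink**: the published polygon is the true footprint scaled
  toward its centroid by √(1−s), so its area is exactly (1−s) of truth;
  s is drawn per polygon from N(0.188, 0.05) clipped to [0, 0.95]. The
  mean 0.188 reproduces the known shortfall structure; the spread is a free
  parameter (only the mean and a scatter are known) and 0.05 keeps every
  polygon's ratio far from the outlier cut. The attribute table reports the
  **true** area, the pipeline sees the **shrunken** polygon — this is the
  reported-vs-geometric discrepancy the adjustment corrects.
- **Reported resettlement**: the true zonal population of the true polygon,
  times lognormal noise exp(N(0, σ²)); σ defaults to 0 (surveys are
  treated as exact) so recovery checks are sharp; multiplicative lognormal
  is the natural noise model for positive, heavy-tailed counts.
- **Derived datasets**: truth × β, then a fraction (default 0.3) of every
  cell's mass spread uniformly over a 2–4 km disk (edge-truncated and
  renormalised per source cell, so totals are exactly β × truth), then
  aggregated to 1–2 km cells. The five default β values 0.47, 0.35, 0.33,
  0.32, 0.16 mirror the bias magnitudes of the five real products. The
  field is static, so a dataset's rasters differ across vintages only in
  metadata.

Every output is a pure function of (config, seed); each stage draws from
its own spawned random stream, so regenerating one artefact never perturbs
another.

What the generator does **not** emulate: urban morphology, terrain or road
covariates, temporal population change, non-convex or multi-part
footprints, and spatially correlated reporting errors. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
recovers known biases under its stated assumptions — not that any real
dataset has a particular accuracy.

## Numerical choices

- Refinement uses exact even splitting (Kronecker product); conservation
  holds to ≤1e−9 relative and is property-tested.
- Reallocation divides each source cell by its in-bounds kernel mass before
  a symmetric convolution, making edge truncation mass-conserving to float
  precision.
- Pairs are written with `%.17g` and read with round-trip float parsing, so
  re-reporting from `pairs.csv` is bit-identical to the original run;
  outputs are sorted by (dataset, id) for byte-stable reruns.
- Degenerate inputs: empty record lists filter to empty; a polygon
  containing no refined centroid extracts 0; a pair set whose reported
  populations sum to 0 makes the bias undefined and raises.

## Scale of the shipped checks

The recovery check in the test suite runs the full default scenario
(307 reservoirs × 5 datasets, 400 × 400 km at 1 km, refine factor 10,
σ = 0, per-polygon shrink fixed at 0.188, fixed b = 0.188) and requires
each dataset's bias to land within ±3 percentage points of (β−1)·100; it
completes in well under a minute, so no larger configuration was needed.
The oracle-equivalence suite covers 105 random grid/polygon instances at
refine factors 1, 2 and 10, including polygons overhanging the grid edge.
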