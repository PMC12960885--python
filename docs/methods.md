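# Methods

## The analysis model

`bcmap` treats a coastal landscape as a stack of co-registered square-cell
rasters (planar metres, 10 m cells by default) plus vector layers (urban
areas, drainage basins, protected areas, field points). The analysis is a
fixed sequence: delimit the coastal domain, compile the habitat map,
patchify, score pressure, overlay protection, validate. All steps are
deterministic; the only randomness in the package sits in the synthetic
scene generator and is fully seeded.

### Coastal domain

The terrestrial domain is the set of land cells with elevation at or below
a threshold (default 2 m — the conventional upper limit for coastal
marshes) that are *reachable* from any sea cell through a 4-connected path
of such cells. Reachability, rather than raw distance to the shore, is the
operational reading of "directly adjacent to the sea": it excludes, with a
single mechanism, low-lying areas cut off by man-made barriers (roads) and
areas behind lakes. Barrier and lake cells are removed from the traversable
set *before* the flood fill — a lake is not a marine connection, so it must
not act as a conduit — and ties at exactly the threshold are included
("2 m or less"). 8-connectivity is available as a switch; 4-connectivity is
the default because edge-sharing is the conservative reading of adjacency.
The submerged domain is the feasibility mask of the satellite SAV product,
taken as given. No hard inland distance cap is imposed; the fringe width is
emergent from the elevation model.

### Habitat compilation

Wetland classes are unioned from the land-cover raster and the vector
inventory; where the two disagree at a cell the vector source wins, because
it is the quality-controlled baseline mapping inside protected areas. The
SAV layer records, per cell, in how many of 5 observation years vegetation
was detected; cells with `count >= min_years` (default 4) are retained.
Retained cells are classified seagrass or other rooted macrophytes by a
per-region rule (all-seagrass, all-other, or overlap with a modelled
potential seagrass distribution); every retained cell receives exactly one
label — mixed meadows exist in reality but the map carries a single class
per cell. Patchification is connected-component labelling per class
(4-connectivity, matching the domain step); patch areas are cell counts
times the cell area, exactly. Each patch is tagged with the drainage basin
holding the majority of its cells.

### Pressure index

Distance classes are closed at the *upper* end (d ≤ 100 m → 4) and
proportion classes at the *lower* end (p ≥ 80 % → 4): one convention,
declared and tested, for boundaries the class table leaves open. The
100/400/1000/5000 m figures are treated as distance thresholds (radii of
the buffer zones), and patch distance is the minimum from any part of the
patch (most-exposed reading; a centroid mode would understate exposure of
elongated meadows). The urban component is implemented twice on purpose —
buffer-ring membership and nearest-distance classification — and the two
constructions are asserted identical in the tests; rings are built at high
arc resolution (`quad_segs=256`) so the polygonal buffer tracks the true
offset curve to ~1e-5 of the radius. Raster stressor layers use the exact
Euclidean distance transform between cell centres.

Basin linking: a patch inside one basin takes that basin's value; spanning
patches take the unrounded arithmetic mean (no rounding rule is imposed on
the cumulative value either, so it may be fractional); patches outside all
basins link to the nearest one within 500 m, and beyond that are excluded
from the basin component (contribution 0, flagged `basin_excluded`).
Submerged and terrestrial patches run through identical scoring rules but
are computed and reported with their realm. The cumulative value is the
plain sum of the three components; the higher-level band 6–12 is inclusive
at 6 (half the maximum).

### Protection overlap and the t test

Protection splits are per cell centre, so protected + unprotected area
equals patch area exactly. Area tables report km² plus integer percentages
rounded half away from zero (printed-table convention); habitat shares are
taken against the delimited coastal area, pressure and protection shares
against each row's own habitat area. For the t test a patch counts as
"inside" when more than half its area is protected; the default sampling
unit is the stratum (mean cumulative value per habitat class × subbasin ×
protection cell) with a patch-level mode available — the appropriate unit
is genuinely ambiguous, so both are exposed. Inside is the first group:
lower pressure under protection yields negative t. Zero pooled variance is
handled explicitly (equal means → t = 0, p = 1).

### Quality control

The 30 m acceptance radius is inclusive and measured to the patch
footprint (boundary distance; zero inside a patch), and matching is
class-aware — distance to the nearest patch *of the observed class* — with
a class-blind mode for sensitivity checks. Persistence-threshold selection
scores each candidate k by balanced accuracy of the `count >= k` mask
against presence/absence references; ties go to the stricter k. A class
absent from the references contributes a vacuous rate of 1.0 inside the
scoring helper (an empty mask scored against all-present references gives
0.5), but the selector refuses one-class reference sets outright, since a
selection based on them would be meaningless.

## The synthetic scene generator

The generator's job is to produce landscapes on which the pipeline's
output is *provable*: every stochastic element is drawn from one seeded
generator, and the ground truth is fixed by construction, not measured
back from the scene.

* **Coastline and elevation.** A sinusoidal coastline separates sea from
  land; elevation ramps linearly from the shore to `coastal_relief`
  (default 15 m), so the ≤ 2 m fringe is an analytically known strip
  (~400 m wide at the defaults). One headland bulge carries a shore-
  parallel road that severs the fringe behind it — a constructed cell set —
  and small lakes sit inside the fringe between habitat bands. The true
  coastal mask is assembled from these known pieces and cross-checked in
  the tests against an independent breadth-first-search oracle.
* **Habitats.** One patch per horizontal band, grown by seeded random
  region growing to exactly `patch_cells` cells (default 120, i.e.
  0.012 km² at 10 m cells): wetlands on the fringe, SAV blobs hugging the
  shore within the feasibility strip. Latitudinal thirds carry the
  regional SAV rules (south all-seagrass, middle model-overlap, north
  all-other), mirroring the real latitudinal classification.
* **Stressors at requested distance classes.** Each patch carries an
  (urban, agriculture) class assignment. A 5×5-cell stressor block is
  placed due east of the patch's easternmost cell at the class-interval
  midpoint (50/250/700/2500 m); class 0 means no stressor. After all
  placement — including basin top-up, below — the nearest distance from
  every patch to every stressor type is recomputed exactly and must fall
  in the requested interval, else the layout is rejected as a
  configuration error. Band spacing at the defaults guarantees
  cross-band stressors cannot undercut any assigned class.
* **Basins.** Horizontal land bands; their modified-land proportion is
  topped up to the configured targets (defaults 10/30/50/70 %, spanning
  basin pressure values 0–3) by painting agriculture into far-field
  columns east of a safety margin, so painting cannot disturb any distance
  class. Achieved proportions (never below the target, up to cell
  granularity) are recorded as the truth.
* **Protection.** Rectangles cover whole patches, lowest cumulative
  pressure first, until the target share (default 31 %) of habitat area is
  protected. Protecting the quietest patches first reproduces the
  direction of the real-world contrast (lower pressure inside
  protection → negative t); it also means the default t is modest, since
  only eight patches exist.
* **SAV detection model.** Year counts are Binomial(5, p) inside true SAV
  (default p = 0.97) and Binomial(5, q) commission noise elsewhere in the
  feasibility strip (default q = 0.15). These defaults were chosen so the
  layer's omission/commission behaviour makes k = 4 the balanced-accuracy
  optimum of the persistence filter — the regime reported for the real
  product — while keeping commission artefacts (a few dozen single-cell
  patches per scene) small relative to true habitat. Setting p = 1, q = 0
  gives a noise-free layer; the exact-recovery scenes use that.
* **Field points.** Sampled uniformly over true habitat cells, displaced
  by isotropic Gaussian GPS noise (default sd 10 m, typical of handheld
  receivers; sd 0 gives 100 % QC accuracy by construction).

What the generator does *not* emulate: real bathymetry and depth-dependent
detectability, salinity gradients, spatially correlated classification
error, partial patch protection, or realistic basin shapes. Passing tests
therefore demonstrate the correctness of the pipeline's logic and
arithmetic on landscapes with known answers — not the accuracy of any real
national map.

## Numerical choices and degenerate inputs

* Distances are exact Euclidean (distance transform between cell centres
  for rasters; GEOS distances for geometries). Cell membership in polygons
  is evaluated at cell centres, making all area splits exact at cell
  resolution; polygon boundaries passing exactly through a cell centre
  fall outside (strict interior test).
* Integer percentages round half away from zero, matching printed-table
  conventions (`compute_percent(1, 8) = 13`).
* Empty stressor layers give distance ∞ → class 0; an empty basin list
  excludes every patch from the basin component; an empty domain clips to
  empty outputs without error; an all-sea elevation grid yields an empty
  land mask.
* The scene generator validates its own feasibility (band heights, grid
  extents for the requested distance classes, region-rule compatibility of
  SAV placements, reachable modified-land targets) and fails loudly with a
  configuration error rather than silently degrading the ground truth.

## Problem sizes

The standard scene is 450 × 768 cells (4.5 × 7.7 km) with 8 patches of 120
cells; a full pipeline run takes well under a second, and the whole test
suite — including 100 randomized 200 × 200 reachability-oracle scenes and
100 ring/distance equivalence layouts — runs in seconds. These sizes give
every geometric mechanism (severance, multi-basin spanning, seaward basin
linking, commission noise) room to occur while keeping brute-force oracles
cheap; nothing in the method is resolution-dependent beyond the stated
10 m cell size.

## Known limitations

* The inside/outside t test treats strata (or patches) as independent
  observations; spatial autocorrelation between neighbouring patches is
  ignored, as in the original index.
* The pressure index is deliberately simple: it does not model water
  quality, eutrophication, hydrological connectivity or erosion, and the
  three components are weighted equally.
* Vector-vs-raster wetland precedence is a declared decision; real
  reconciliation between national products may be more nuanced.
* With imperfect SAV detection the compiled patch mosaic differs from the
  constructed truth (missing cells, commission artefacts); truth-equality
  assertions therefore apply only to noise-free configurations, and the
  default-scene comparisons are reported as approximate.
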