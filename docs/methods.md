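# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical decisions a user should
know before trusting a number.

## Rasters and geometry

All stages operate on aligned rasters: same shape, cell size (meters)
and top-left origin; nothing is resampled. Pixel (r, c) has its center
at `origin + ((c + 0.5), −(r + 0.5)) · cell_size`; all distance
computations are center-to-center. Nodata pixels are *not landscape*:
they are excluded from the total landscape area `A_T`, which is why
masking the urban union out of a grid shrinks the landscape rather
than adding background (the minimum-land-pixel cell filter downstream
makes the same assumption). The class vocabulary is
urban / high-density urban / forest / wetland / pasture / agriculture /
other; high-density urban is a subclass of urban and is folded into it
for every metric. The crosswalk from a map product's native legend is
a user-supplied two-column CSV — the package deliberately ships no
hard-coded crosswalk for any real map series, only the identity table
used for synthetic data.

On-disk formats: ESRI ASCII grid (complete header with declared
NODATA_value required — a missing cell size or nodata declaration is
an error, never guessed) and single-band TIFF with the grid geometry
carried as JSON in the ImageDescription tag.

## Patch metrics

Patches are maximal connected components of the focal class,
8-neighbour by default (the convention of the standard FRAGSTATS-style
toolchain); 4-neighbour is a flag. Edges are always counted over
4-neighbour pixel *faces*, because only faces have a physical length
(one cell size per face); diagonal adjacency has no face. Two boundary
policies exist: `exclude` (default) counts only faces against
non-focal *land* pixels, `include` also counts faces against nodata
and the grid border. The default is the conservative choice — border
and nodata contact is not evidence of fragmentation — and both are
tested.

`EDGE_AREA` is reported as meters of edge per *hectare* of focal area
(configurable to per m²). For mean patches of several hectares this is
the scale on which published edge-to-area values of a few hundred are
arithmetically consistent; the choice is recorded in the metric
metadata.

A class with zero patches yields NaN indices and a `defined=False`
flag — never zero, which would silently corrupt the downstream
regressions. Cells whose response is undefined are dropped from each
regression, and the weight matrix is rebuilt on the retained subset.

## Change scenarios

Forest change between aligned dates t1, t2 partitions land pixels into
unchanged forest (F∩F), deforested (F∩¬F), reforested (¬F∩F) and
never-forest. Scenario landscapes place a single background class
behind the scenario's forest mask (metrics for a focal class are
invariant to background labels, which a test asserts). Distances from
change sites to unchanged forest use an exact Euclidean distance
transform seeded on the unchanged set; category pixels are never
unchanged pixels, so zero distances cannot enter the mean.

## Grid stage

Tiling anchors non-overlapping `cell_pixels × cell_pixels` windows at
the raster origin; partial right/bottom windows are kept, flagged, and
subjected to the same minimum-land filter (default 25% of a full
cell, i.e. 2,500 of 10,000 pixels at the reference 3 km scale), which
makes the border-handling choice nearly inert. Each retained cell is
its own landscape (A_T = the cell's land area). Covariate summaries
are means and SDs over land pixels. Increments are *signed pixel
counts* per class between the two dates, not areas — the scale on
which the increment regressions are specified. Slope, when not
supplied, comes from elevation by Horn's 8-neighbour gradient (the
documented method of the common GIS implementation), in degrees.
"Distance to urban" is the exact Euclidean distance to any urban pixel
of the reference year — an assumption, since named city centroids are
an alternative reading; the reference raster is explicit in the API.

## Spatial-error model

`y = Xβ + ε, ε = λWε + ξ` with `ξ ~ N(0, σ²I)`. W links each cell to
its k = 8 nearest centroids (Euclidean; ties broken by the lower cell
index, making the matrix reproducible), row-standardized by default
with a raw-binary flag. Estimation concentrates β and σ² out of the
likelihood: for trial λ, OLS on the filtered data `(I − λW)y,
(I − λW)X` gives the profile log-likelihood

    ℓ(λ) = −n/2 (log 2π + 1) − n/2 log σ̂²(λ) + Σᵢ log|1 − λωᵢ|,

with ωᵢ the (once-computed, cached) eigenvalues of W. λ is searched by
bounded Brent over the stationary interval `(1/ω_min + 10⁻⁴,
1/ω_max − 10⁻⁴)` to tolerance 10⁻⁸; a fine-grid scan oracle in the
tests confirms the optimizer lands on the global profile optimum at
small n. β standard errors come from the GLS covariance at λ̂, λ's
from the numerical curvature of the profile likelihood. Failure modes
(rank-deficient design, missing values, non-convergence) raise — no
silent fallback.

AIC counts p + 2 free parameters (coefficients, λ, σ²). Term retention
is an exhaustive subset search (guarded to ≤ 12 candidates) with the
intercept searched like any other term, so a best-fit model may have
none. Ties resolve to the smaller model. Significance uses asymptotic
z-tests with the two-star convention (p < 0.01 / p < 0.05) and no
multiple-testing correction — the convention of the reporting format
it reproduces. The increment-on-area-change regressions run through
the same spatial machinery by default (a non-spatial mode exists),
since nothing in their specification suggests a different error model.

## Peak analysis

A fitted response with terms `b₁x + b₂x²` has its vertex at
`−b₁/(2b₂)`, a maximum iff b₂ < 0. Locations are reported to one
decimal (0.1 km, 0.1°) and rates to two. Shift rates between dates
are computed, by default, from the *rounded* locations — the
convention under which printed locations and printed rates are
mutually consistent — with the absolute annual rate left unrounded
before the relative-rate division (rate / earlier location); an
unrounded mode exists. Predicted curves evaluate Xβ̂ along one
predictor with every other term held at a supplied value (typically
the sample mean). A fit lacking a squared term has no interior peak
and is reported as such, never guessed.

## Synthetic landscapes

The generator exists so that every stage — metrics, scenarios, tiling,
regression, peaks — runs against data with known structure. It is a
pure function of its recipe (one seeded generator per recipe).

**Composition and configuration.** Landscapes come from a
modified-random-clusters process: a Bernoulli lattice at marking
probability `0.45 · clumpiness` (kept below the 4-neighbour site
percolation threshold) is labeled into clusters; unmarked pixels
within 2 cells join the nearest cluster's basin; farther pixels draw
iid. Whole basins are assigned to classes greedily against running
area deficits, which pins realized composition within about two
percentage points of the request at 200 × 200 and above. Two classes
are additionally *concentrated*: most urban accretes around a few city
centers (plus a small scattered-village share), and most forest around
a few upland blocks — the geography that creates a distance-to-urban
gradient for sprawl analysis and open lowland where regrowth can
establish away from forest. With concentration disabled the generator
is a plain neutral-landscape model, in which higher clumpiness
strictly increases mean patch size and decreases edge density at
fixed composition; with concentration on, that monotonicity applies
to the unconcentrated classes only.

**Change.** Defaults describe a decade of strong dynamics on a
reforesting, urbanising landscape: 18% of the initial forest cleared,
a slightly larger area reforested (net forest gain of about +1–2%),
and 8% urban growth. Deforestation is seeded in the forest erosion
core (≥ 2 pixels inside the boundary — the interior bias) as clustered
clearings, half in large 9 × 9 blocks (pasture development, able to
cut across a patch) and half in 5 × 5 blocks, topped up with single
pixels. Reforestation is mostly coherent edge parcels grown
geodesically within a 3-pixel band along the forest boundary,
constrained away from the inter-patch medial lines so regrowth
thickens a patch without welding neighbours; a 15% share (plus any
edge shortfall) establishes as small isolated patches beyond the edge
bands — the process that lets the patch count grow during net
reforestation. Urban growth samples non-urban, non-wetland land with
probability `exp(−d/decay)` in the distance to existing urban
(decay 1,500 m, a suburban-belt width); it may consume forest, and
the change map counts such pixels as deforested. Under these defaults
the generated decade reproduces, qualitatively and robustly across
seeds, the fragmentation syndrome the pipeline is built to detect:
reforested sites lie farther from unchanged forest than deforested
sites (≈ 68 vs 53 m), forest mean patch area falls while total forest
area and edge density rise, the deforestation-only scenario shows
falling mean patch area with rising edge-to-area while the
reforestation-only scenario shows the opposite, and the urban
edge-to-area peak moves outward between dates.

**What it does not emulate.** Real class geometry (shorelines,
topographic control of land cover), classification error and
inter-map inconsistency, multi-date urban densification, and any
calibration to a particular region's maps. Passing the end-to-end
tests therefore demonstrates that the *pipeline* detects a known
embedded signal — not that any particular real landscape behaves this
way.

**Regression draws.** `generate_sem_data` draws exactly from the
spatial-error model on a jittered integer lattice (jitter breaks kNN
ties), `y = Xβ + (I − λW)⁻¹ξ`, refusing λ outside the stationary
interval of the realized W.

## Testing and problem sizes

Oracles are deliberately naive: flood-fill patch delineation,
exhaustive face counting, all-pairs minimum distances, fine-grid scans
of the profile likelihood. Statistical checks use seeded replicates:
parameter recovery runs 100 antithetic pairs at n = 400 (pairing each
noise draw ξ with −ξ cancels the linear noise term in the Monte-Carlo
mean, so the comparison to truth measures estimator bias rather than
draw luck — the profile RSS is even in ξ, making the pair means exact
to optimizer tolerance); the intercept-test type-I error uses 100
null replicates at n = 400; end-to-end checks use one 600 × 600
landscape pair with 30-pixel (900 m) analysis cells, a size at which
the full pipeline runs in well under a minute while retaining ~400
regression cells. The reference configuration (100-pixel cells,
2,500-pixel land filter, k = 8) remains the default for real-scale
maps.

## Known limitations

- The spatial-error fit computes dense eigenvalues of W once per
  weight matrix: fine into the low thousands of cells, not for
  hundred-thousand-cell problems.
- Exhaustive AIC search is exponential in the candidate count and
  guarded at 12 terms.
- The peak-shift convention (rounded locations) exists to make
  printed locations and rates mutually consistent; use the unrounded
  mode for downstream arithmetic.
- Only 4/8 connectivity and square pixels are supported; no
  reprojection, resampling or vector overlays.
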