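# fragscape

Landscape-fragmentation dynamics from categorical land-cover rasters:
patch-based fragmentation indices, counterfactual forest-change
scenarios, and spatial-error regression of fragmentation on
biophysical and socioeconomic drivers — the analysis toolkit for
studying how urban sprawl, deforestation and reforestation reshape a
landscape between two or three map dates. It is aimed at landscape
ecologists and spatial analysts who have 30 m class maps (forest,
urban, wetland, pasture, …) for multiple years and want to go from
pixels to defensible statements like "the peak of urban fragmentation
moved outward by 0.19 km per year".

## What it computes

**Class-level fragmentation indices** over patches (maximal connected
components, 8-neighbour by default; edges counted over 4-neighbour
pixel faces of length equal to the cell size):

- mean patch area `AREA_MN = (Σ aᵢ / n) / 10⁴` (ha),
- largest patch index `LPI = 100 · max aᵢ / A_T` (%),
- edge density `ED = 10⁴ · Σ eᵢ / A_T` (m ha⁻¹ of landscape),
- edge-to-area ratio `EDGE_AREA = Σ eᵢ / A` (per focal area),

with `aᵢ, eᵢ` patch area and edge, `A` focal-class area and `A_T` the
land (non-nodata) area of the landscape.

**Counterfactual change scenarios** between two dates: pixels are
classed as unchanged forest, deforested, reforested, or never-forest;
the *deforestation-only* landscape keeps only unchanged forest, the
*reforestation-only* landscape unions both dates' forest. Comparing the
indices across scenarios attributes the fragmentation signal to one
process. Distance statistics (exact Euclidean, pixel centers) measure
whether change concentrates at forest edges or interiors, and an
urban-union mask recomputes forest metrics "outside urban areas".

**Gridded spatial regression**: the landscape is tiled into large
square cells (3 km × 3 km = 100 × 100 pixels by default; cells with
fewer than 2,500 land pixels are discarded), per-cell indices and
covariate summaries (distance to urban *D*, slope mean/SD, elevation,
population density) feed a spatial-error model

    y = Xβ + ε,  ε = λWε + ξ,

with `W` an 8-nearest-neighbour row-standardized weight matrix over
cell centroids, estimated by maximum likelihood via the concentrated
profile likelihood in λ (eigenvalue form of log|I − λW|). Model terms
are retained by exhaustive minimum-AIC search; intercept-only fits of
index increments test whether fragmentation changed between dates.

**Peak-shift analysis**: fitted quadratics in *D* have a vertex at
`−b₁/(2b₂)`; tracking that vertex across dates yields absolute
(km yr⁻¹) and relative (% yr⁻¹) sprawl rates.

A seeded synthetic-landscape generator (modified random clusters with
concentrated urban/forest geography, edge-parcel reforestation,
interior clearings, distance-decayed urban growth, and exact
spatial-error draws) makes the whole pipeline testable with no
external data.

## Worked example

```sh
fragscape all --outdir out --shape 250 250 --seed 4
```

simulates a 250 × 250 paired-year landscape and runs both analyses.
Selected output (this exact invocation):

`out/island/distances.json` —

```json
{
  "deforested_mean_distance_m": 52.97,
  "reforested_mean_distance_m": 68.54,
  "deforested_closer_percent": 22.72
}
```

Reforested sites sit on average 68.5 m from unchanged forest and
deforested sites 53.0 m — deforestation strikes ~23% closer to the
forest interior, the geometry that makes deforestation the stronger
fragmenting force. `out/island/scenario_changes.csv` quantifies that:
removing only the deforested pixels drops the forest mean patch area
by 20.2% and raises its edge-to-area ratio by 59.9%, while
reforestation alone *increases* the mean patch area by 16.7%.

`out/grid/peak_shifts.csv` —

```text
response,from,to,absolute_rate,relative_rate_percent
EDGE_AREA_U,1991,2000,0.03,11.11
```

The urban edge-to-area quadratic in distance-to-urban peaks at 0.3 km
in the first year and 0.6 km in the second (`out/grid/peaks.csv`): the
belt of small, irregular urban patches moved outward at 0.03 km per
simulated year — urban sprawl read off a fragmentation index.

The same computations are available as library calls
(`run_island_wide`, `run_grid_analysis`, and the per-module functions
they compose); see `docs/methods.md` for the model details and
parameter choices.

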