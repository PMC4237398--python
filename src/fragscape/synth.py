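"""Synthetic landscapes, paired-year change, covariates, and SEM draws.

Every pipeline stage is testable without any map download: this module
generates (a) clustered categorical landscapes by the modified random
clusters method (percolation clusters on a Bernoulli lattice assigned
to classes by target proportion, remaining pixels filled from the
nearest assigned cluster); (b) paired-year change emulating the
structure of a reforesting, urbanising landscape — reforestation along
forest edges, deforestation in forest interiors, and urban growth with
probability decaying in distance from existing urban (sprawl); (c)
covariate surfaces (elevation, slope, population density, distance to
urban); and (d) exact draws from the spatial-error regression model
with known coefficients and spatial parameter.

Change-rate defaults reflect a decade of strong land-cover dynamics on
a reforesting island: about 18% of the initial forest deforested, a
slightly larger reforested area (ratio ~1.1, net forest gain ~2%), and
8% urban growth. Every generator is a pure function of its recipe: the
same seed yields the same output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .change import ChangeCategory, ForestChangeMap
from .raster import DEFAULT_VOCABULARY, CovariateGrid, LandCoverGrid, TargetClass
from .sem import SpatialWeights, build_knn_weights
from .tiling import distance_to_urban_surface, horn_slope

__all__ = [
    "LandscapeRecipe",
    "ChangeRecipe",
    "SEMRecipe",
    "generate_landscape",
    "generate_change_pair",
    "generate_covariates",
    "generate_sem_data",
]

# Bernoulli marking probability stays below the 4-neighbour site
# percolation threshold (~0.593) so no giant cluster swallows the map.
_MAX_MARK_P = 0.45


@dataclass
class LandscapeRecipe:
    """Recipe for one clustered categorical landscape."""

    shape: tuple[int, int] = (400, 400)
    cell_size: float = 30.0
    proportions: dict[int, float] = field(
        default_factory=lambda: {
            TargetClass.FOREST: 0.40,
            TargetClass.URBAN: 0.11,
            TargetClass.PASTURE: 0.25,
            TargetClass.WETLAND: 0.03,
        }
    )
    clumpiness: float = 0.6
    #: urban cover is concentrated around this many city centers (the
    #: remainder is scattered as small compact "villages"), producing the
    #: core-to-hinterland distance gradient that urban-sprawl analyses
    #: presuppose; 0 disables concentration
    urban_centers: int = 3
    urban_scatter_share: float = 0.15
    #: forest is likewise concentrated into this many upland blocks
    #: (think of a mountain interior), leaving open lowland regions far
    #: from any forest where isolated regrowth can later establish
    forest_centers: int = 2
    forest_scatter_share: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.clumpiness <= 1):
            raise ValueError("clumpiness must lie in [0, 1]")
        total = sum(self.proportions.values())
        if any(p < 0 for p in self.proportions.values()) or total > 1 + 1e-9:
            raise ValueError("proportions must be nonnegative and sum to <= 1")


@dataclass
class ChangeRecipe:
    """Recipe for a paired-year change on top of a base landscape."""

    edge_reforestation_fraction: float = 0.20
    interior_deforestation_fraction: float = 0.18
    urban_growth_fraction: float = 0.08
    #: e-folding distance of sprawl probability, meters — roughly the
    #: width of the suburban belt into which new urban spills
    urban_distance_decay: float = 1500.0
    #: minority share of reforestation establishing as small isolated
    #: patches (regrowth on abandoned fields away from existing forest);
    #: the rest accretes along forest edges. Whatever the edge rings
    #: cannot accommodate also spills into isolated regrowth so the
    #: total reforested area honours the requested rate.
    isolated_reforestation_share: float = 0.15
    #: half-width in pixels of a deforestation clearing (2 -> 5 x 5)
    clearing_radius: int = 2
    #: number of dilation rings over which edge regrowth spreads
    reforestation_rings: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "edge_reforestation_fraction",
            "interior_deforestation_fraction",
            "urban_growth_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.urban_distance_decay <= 0:
            raise ValueError("urban_distance_decay must be positive")


@dataclass
class SEMRecipe:
    """Recipe for an exact draw from the spatial-error model."""

    n: int = 400
    beta: tuple[float, ...] = (1.0, 2.0)
    lam: float = 0.5
    sigma: float = 1.0
    k: int = 8
    seed: int = 0


def generate_landscape(recipe: LandscapeRecipe) -> LandCoverGrid:
    """Clustered categorical landscape by modified random clusters.

    A Bernoulli lattice at marking probability proportional to
    ``clumpiness`` is labeled into 4-connected clusters; clusters are
    assigned to classes largest-first against the running class-area
    deficits, and unmarked pixels inherit the class of the nearest
    assigned pixel. Higher clumpiness yields larger marking clusters
    and hence larger patches at identical composition.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    shape = tuple(recipe.shape)
    classes = list(recipe.proportions)
    props = np.array([recipe.proportions[c] for c in classes], dtype=float)
    other = max(0.0, 1.0 - props.sum())
    classes.append(TargetClass.OTHER)
    props = np.append(props, other)

    if recipe.clumpiness == 0:
        flat = rng.choice(classes, size=shape[0] * shape[1], p=props / props.sum())
        values = flat.reshape(shape)
    else:
        p_mark = _MAX_MARK_P * recipe.clumpiness
        marked = rng.random(shape) < p_mark
        labels, n_clusters = ndimage.label(marked)  # 4-connected clusters
        if n_clusters == 0:
            marked[tuple(rng.integers(0, s) for s in shape)] = True
            labels, n_clusters = ndimage.label(marked)
        # unmarked pixels within a short reach of a cluster join that
        # cluster's basin; pixels farther out draw iid from the class
        # proportions, so sparse marking (low clumpiness) yields a
        # fine-grained mosaic rather than giant fill regions
        dist, (ir, ic) = ndimage.distance_transform_edt(
            ~marked, return_indices=True
        )
        near = dist <= 2.0
        basins = np.where(near, labels[ir, ic], 0)
        # whole basins (cluster + near fill) are assigned to classes
        # greedily against the running area deficits, which keeps the
        # realized composition close to the request
        sizes = np.bincount(basins.ravel(), minlength=n_clusters + 1)[1:]
        total = float(sizes.sum())
        # concentrated classes live only in basins (the far fill skips
        # them), so their quotas are map-wide; everything else shares
        # the remaining basin area in proportion
        target = props / props.sum() * float(values_size := shape[0] * shape[1])
        assigned = np.zeros(len(classes))
        cluster_class = np.zeros(n_clusters + 1, dtype=np.int64)
        taken = np.zeros(n_clusters, dtype=bool)

        # urban and forest are spatially concentrated: most of each
        # accretes around a few centers (nearest basins first), the
        # rest lands as small scattered pieces. For urban this gives
        # the core-fringe-hinterland distance gradient; for forest it
        # emulates upland forest blocks with open lowlands in between.
        rsum = np.bincount(basins.ravel(),
                           np.indices(shape)[0].ravel(),
                           minlength=n_clusters + 1)[1:]
        csum = np.bincount(basins.ravel(),
                           np.indices(shape)[1].ravel(),
                           minlength=n_clusters + 1)[1:]
        cent = np.column_stack([rsum, csum]) / np.maximum(sizes, 1)[:, None]
        frozen: list[int] = []
        for cls, n_centers, scatter in (
            (TargetClass.URBAN, recipe.urban_centers, recipe.urban_scatter_share),
            (TargetClass.FOREST, recipe.forest_centers, recipe.forest_scatter_share),
        ):
            if cls not in classes:
                continue
            j_cls = classes.index(cls)
            if n_centers <= 0 or target[j_cls] <= 0:
                continue
            centers = rng.uniform(0, shape, size=(n_centers, 2))
            d_basin = np.min(
                np.hypot(cent[:, None, 0] - centers[None, :, 0],
                         cent[:, None, 1] - centers[None, :, 1]),
                axis=1,
            )
            core_target = (1.0 - scatter) * target[j_cls]
            for ci in np.argsort(d_basin):
                if assigned[j_cls] >= core_target:
                    break
                if taken[ci]:
                    continue
                cluster_class[ci + 1] = cls
                assigned[j_cls] += sizes[ci]
                taken[ci] = True
            piece_cap = max(9.0, 0.0005 * total)
            for ci in rng.permutation(n_clusters):
                if assigned[j_cls] >= target[j_cls]:
                    break
                if taken[ci] or sizes[ci] > piece_cap:
                    continue
                cluster_class[ci + 1] = cls
                assigned[j_cls] += sizes[ci]
                taken[ci] = True
            assigned[j_cls] = max(assigned[j_cls], target[j_cls])  # freeze
            frozen.append(j_cls)

        # the unconcentrated classes also receive the far iid fill, so
        # their basin quotas are the map-wide target minus that share
        rest = [j for j in range(len(classes)) if j not in frozen]
        p_rest = props[rest].sum() if rest else 1.0
        far_area = float((dist > 2.0).sum())
        for j in rest:
            target[j] = max(
                0.0,
                props[j] / props.sum() * values_size
                - props[j] / p_rest * far_area,
            )

        order = np.argsort(sizes)[::-1]  # largest basins first
        for ci in order:
            if taken[ci]:
                continue
            deficit = target - assigned
            for j_cls in frozen:
                deficit[j_cls] = -np.inf
            j = int(np.argmax(deficit))
            cluster_class[ci + 1] = classes[j]
            assigned[j] += sizes[ci]
        values = cluster_class[basins]
        far = ~near
        if far.any():
            # iid fill from the unconcentrated classes only: stray
            # single urban or forest pixels would erase the distance
            # gradients the concentration just built
            p_fill = props.copy()
            for j_cls in frozen:
                p_fill[j_cls] = 0.0
            values[far] = rng.choice(
                classes, size=int(far.sum()), p=p_fill / p_fill.sum()
            )
    return LandCoverGrid(
        values,
        cell_size=recipe.cell_size,
        nodata=-9999,
        origin=(0.0, 0.0),
        vocabulary=DEFAULT_VOCABULARY,
    )


def _choose(rng: np.random.Generator, mask: np.ndarray, n: int,
            p: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample n pixel coordinates from a boolean mask (capped at its size)."""
    rows, cols = np.nonzero(mask)
    n = min(n, len(rows))
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    if p is not None:
        p = p / p.sum()
    idx = rng.choice(len(rows), size=n, replace=False, p=p)
    return rows[idx], cols[idx]


def generate_change_pair(
    base: LandCoverGrid, recipe: ChangeRecipe
) -> tuple[LandCoverGrid, LandCoverGrid, ForestChangeMap]:
    """A (t1, t2) land-cover pair plus its ground-truth change map.

    t1 is the base landscape. Three processes act on it:

    * deforestation — clustered clearings (about (2r+1)^2 pixels each)
      seeded in the forest erosion core (>= 2 pixels inside the
      boundary, interior bias) and grown over the forest without
      clipping, so large clearings can reach and sever patch edges;
      cleared pixels become pasture;
    * reforestation — mostly accretion along forest edges spread over
      ``reforestation_rings`` successive dilation rings, plus a small
      ``isolated_reforestation_share`` establishing as compact new
      patches 3-12 pixels from existing forest (regrowth on abandoned
      fields), which is what lets the patch count grow;
    * urban growth — drawn from non-urban, non-wetland land with
      probability exp(-d / decay) in the distance d to existing urban
      (sprawl); it may consume forest, and such pixels count as
      deforested in the truth map.

    Rates are fractions of the t1 forest (change) and t1 urban (growth)
    pixel counts.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    land = base.land_mask
    f1 = base.class_mask(TargetClass.FOREST) & land
    u1 = base.class_mask(TargetClass.URBAN) & land
    wet = base.class_mask(TargetClass.WETLAND) & land
    if not f1.any() or not u1.any():
        raise ValueError("base landscape must contain forest and urban pixels")
    n_forest = int(f1.sum())
    struct8 = np.ones((3, 3), bool)
    r = recipe.clearing_radius
    blob = np.ones((2 * r + 1, 2 * r + 1), bool)

    # interior-seeded clustered deforestation
    core = ndimage.binary_erosion(f1, iterations=2)
    n_def = round(recipe.interior_deforestation_fraction * n_forest)
    if n_def > 0 and not core.any():
        warnings.warn(
            "forest erosion core is empty; deforestation falls back to "
            "the full forest mask", stacklevel=2,
        )
        core = f1
    defo = np.zeros_like(f1)
    if n_def > 0:
        # half the cleared area in large (pasture-development) clearings
        # that can cut across patches, half in small ones, remainder as
        # single-pixel nibbles
        big_blob = np.ones((4 * r + 1, 4 * r + 1), bool)
        for shape_, share in ((big_blob, 0.5), (blob, 0.5)):
            quota = round(share * n_def)
            n_blobs = max(1, round(quota / shape_.sum()))
            sr, sc = _choose(rng, core & ~defo, n_blobs)
            seeds = np.zeros_like(f1)
            seeds[sr, sc] = True
            defo |= ndimage.binary_dilation(seeds, structure=shape_) & f1
        deficit = n_def - int(defo.sum())
        if deficit > 0:  # top up with single-pixel clearings in the core
            xr, xc = _choose(rng, core & ~defo, deficit)
            defo[xr, xc] = True
        elif deficit < 0:  # trim overshoot
            rr_, cc_ = np.nonzero(defo)
            drop = rng.choice(len(rr_), size=-deficit, replace=False)
            defo[rr_[drop], cc_[drop]] = False

    # reforestation: edge accretion over successive rings ...
    n_ref = round(recipe.edge_reforestation_fraction * n_forest)
    n_iso = round(recipe.isolated_reforestation_share * n_ref)
    n_edge = n_ref - n_iso
    refo = np.zeros_like(f1)
    open_land = land & ~u1 & ~wet
    rings = max(1, recipe.reforestation_rings)
    # edge accretion as coherent parcels: seeds on the first ring grow
    # geodesically within a strip `rings` pixels wide along the t1
    # forest edge — abandoned fields regrowing as connected pieces
    dband = ndimage.distance_transform_cdt(~f1, metric="chessboard")
    # parcels grow only where a single t1 patch is within reach, so
    # regrowth thickens edges without welding neighbouring patches
    patches = ndimage.label(f1, structure=struct8)[0].astype(np.int64)
    _, (pir, pic) = ndimage.distance_transform_edt(~f1, return_indices=True)
    nearest_patch = patches[pir, pic]
    touches_two = (
        ndimage.maximum_filter(nearest_patch, size=3)
        != ndimage.minimum_filter(nearest_patch, size=3)
    )
    strip = open_land & (dband >= 1) & (dband <= rings) & ~touches_two
    for _ in range(6):  # seed more parcels until the quota is met
        remaining = n_edge - int(refo.sum())
        if remaining <= 0:
            break
        seed_zone = strip & (dband == 1) & ~refo
        n_seeds = max(1, round(remaining / 16))
        sr, sc = _choose(rng, seed_zone, n_seeds)
        if len(sr) == 0:
            break
        seeds = np.zeros_like(f1)
        seeds[sr, sc] = True
        parcels = ndimage.binary_dilation(
            seeds, structure=struct8, iterations=rings + 2, mask=strip
        )
        grown = parcels & ~refo
        excess = int(refo.sum() + grown.sum()) - n_edge
        if excess > 0:
            rr_, cc_ = np.nonzero(grown)
            drop = rng.choice(len(rr_), size=excess, replace=False)
            grown[rr_[drop], cc_[drop]] = False
        refo |= grown
    fcur = f1 | refo

    # ... plus isolated regrowth patches a few pixels off the forest;
    # edge capacity the parcels could not supply spills over here
    n_iso += max(0, n_edge - int(refo.sum()))
    if n_iso > 0:
        # keep a standoff beyond the edge bands so new patches detach
        clear = open_land & (dband >= rings + 1) & ~refo
        for _ in range(6):
            remaining = n_iso - int((refo & clear).sum())
            if remaining <= 0:
                break
            sr, sc = _choose(rng, open_land & (dband >= rings + 2) & ~refo,
                             max(1, round(remaining / 15)))
            if len(sr) == 0:
                break
            seeds = np.zeros_like(f1)
            seeds[sr, sc] = True
            iso = ndimage.binary_dilation(seeds, structure=blob) & clear
            grown = iso & ~refo
            excess = int((refo & clear).sum() + grown.sum()) - n_iso
            if excess > 0:
                rr_, cc_ = np.nonzero(grown)
                drop = rng.choice(len(rr_), size=excess, replace=False)
                grown[rr_[drop], cc_[drop]] = False
            refo |= grown
    fcur = f1 | refo

    values2 = base.values.copy()
    values2[defo] = TargetClass.PASTURE
    values2[refo] = TargetClass.FOREST
    f2 = (f1 & ~defo) | refo

    # distance-decayed urban growth; sprawl may consume forest
    n_urb = round(recipe.urban_growth_fraction * int(u1.sum()))
    if n_urb > 0:
        dist = ndimage.distance_transform_edt(~u1, sampling=base.cell_size)
        candidates = land & ~u1 & ~wet
        weights = np.exp(-dist[candidates] / recipe.urban_distance_decay)
        ur, uc = _choose(rng, candidates, n_urb, p=weights)
        values2[ur, uc] = TargetClass.URBAN
        new_urb = np.zeros_like(u1)
        new_urb[ur, uc] = True
        f2 &= ~new_urb

    grid_t2 = base.with_values(values2)

    cats = np.full(base.shape, ChangeCategory.NODATA, dtype=np.int8)
    cats[land] = ChangeCategory.NEVER_FOREST
    cats[f1 & f2] = ChangeCategory.UNCHANGED_FOREST
    cats[f1 & ~f2] = ChangeCategory.DEFORESTED
    cats[~f1 & f2] = ChangeCategory.REFORESTED
    truth = ForestChangeMap(cats, base.cell_size, base.origin)
    return base, grid_t2, truth


def generate_covariates(
    grid: LandCoverGrid, seed: int = 0, relief: float = 800.0
) -> dict[str, CovariateGrid]:
    """Covariate surfaces consistent with one landscape.

    elevation — smoothed Gaussian noise rescaled to [0, relief] meters;
    slope — Horn gradient of that elevation, degrees, clipped to [0, 45];
    popden — sum of Gaussian kernels centered on urban patches, scaled
    by patch area (persons per km^2);
    D — exact Euclidean distance to the urban class, meters.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    sigma = max(shape) / 12
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    span = noise.max() - noise.min()
    elev_vals = (noise - noise.min()) / (span if span > 0 else 1.0) * relief
    elev = CovariateGrid(elev_vals, cell_size=grid.cell_size,
                         nodata=-9999.0, origin=grid.origin)
    slope = horn_slope(elev)
    slope.values = np.clip(slope.values, 0.0, 45.0)

    urban = grid.class_mask(TargetClass.URBAN)
    dens = np.zeros(shape)
    if urban.any():
        labels, n = ndimage.label(urban, structure=np.ones((3, 3), bool))
        centers = ndimage.center_of_mass(urban, labels, range(1, n + 1))
        areas = ndimage.sum_labels(urban, labels, range(1, n + 1))
        rows, cols = np.indices(shape)
        for (cr, cc), a in zip(centers, areas):
            reach = 10.0 + np.sqrt(a)  # larger patches spread farther
            d2 = (rows - cr) ** 2 + (cols - cc) ** 2
            dens += a * np.exp(-d2 / (2 * reach**2))
        dens *= 5000.0 / max(dens.max(), 1e-12)  # peak density persons/km^2
    popden = CovariateGrid(dens, cell_size=grid.cell_size,
                           nodata=-9999.0, origin=grid.origin)
    out = {"elev": elev, "slope": slope, "popden": popden}
    if urban.any():
        out["D"] = distance_to_urban_surface(grid)
    return out


def generate_sem_data(
    recipe: SEMRecipe,
) -> tuple[np.ndarray, np.ndarray, SpatialWeights, dict]:
    """Exact draw y = X beta + (I - lam W)^{-1} xi on jittered lattice points.

    X has a leading column of ones when len(beta) > 1; remaining columns
    are standard normal. Returns (y, X, W, truth) with the generating
    parameters in ``truth``.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n
    side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    pts = np.column_stack([gx.ravel()[:n], gy.ravel()[:n]])
    pts += rng.uniform(-0.25, 0.25, size=pts.shape)  # break lattice ties
    W = build_knn_weights(pts, k=recipe.k, standardize=True)

    lo, hi = W.stationary_interval
    if not (lo < recipe.lam < hi):
        raise ValueError(
            f"lam={recipe.lam} outside the stationary interval ({lo:.3f}, {hi:.3f})"
        )
    p = len(recipe.beta)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    xi = rng.normal(0.0, recipe.sigma, size=n)
    A = sparse.eye(n, format="csc") - recipe.lam * W.w.tocsc()
    eps = spsolve(A, xi)
    y = X @ np.asarray(recipe.beta) + eps
    truth = {
        "beta": np.asarray(recipe.beta, dtype=float),
        "lam": recipe.lam,
        "sigma": recipe.sigma,
        "centroids": pts,
    }
    return y, X, W, truth
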