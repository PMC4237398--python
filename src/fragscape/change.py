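"""Forest-change classification, counterfactual scenarios, distance statistics.

Between two dates every land pixel falls in exactly one of four change
categories: unchanged forest (forest at both dates, the F_F reference
set), deforested (forest only at t1), reforested (forest only at t2),
or never-forest. Two counterfactual landscapes isolate one process each:

* deforestation-only — the t2 forest with the reforested pixels removed,
  i.e. exactly the unchanged forest;
* reforestation-only — the union of the t1 and t2 forests, i.e. no
  deforestation ever happened.

Comparing the four indices across {t1, t2, deforestation-only,
reforestation-only} attributes the fragmentation signal to one process.
The urban mask variant removes the union of the two dates' urban pixels
from the landscape itself (they become nodata, shrinking A_T), which is
how "forest outside urban areas" metrics are obtained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import (
    DEFAULT_VOCABULARY,
    LandCoverGrid,
    TargetClass,
    require_aligned,
)

__all__ = [
    "ChangeCategory",
    "ForestChangeMap",
    "ScenarioGrid",
    "classify_forest_change",
    "build_scenario",
    "apply_urban_mask",
    "mean_distance_to_unchanged",
    "relative_change",
    "SCENARIO_TAGS",
]


class ChangeCategory:
    NEVER_FOREST = 0
    UNCHANGED_FOREST = 1
    DEFORESTED = 2
    REFORESTED = 3
    NODATA = -1


SCENARIO_TAGS = (
    "TRUE_T1",
    "TRUE_T2",
    "DEFORESTATION_ONLY",
    "REFORESTATION_ONLY",
)


@dataclass
class ForestChangeMap:
    """Per-pixel change categories between two dates."""

    categories: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    t1: int | None = None
    t2: int | None = None

    def mask(self, category: int) -> np.ndarray:
        return self.categories == category

    @property
    def land_mask(self) -> np.ndarray:
        return self.categories != ChangeCategory.NODATA

    def counts(self) -> dict[str, int]:
        c = self.categories
        return {
            "unchanged_forest": int((c == ChangeCategory.UNCHANGED_FOREST).sum()),
            "deforested": int((c == ChangeCategory.DEFORESTED).sum()),
            "reforested": int((c == ChangeCategory.REFORESTED).sum()),
            "never_forest": int((c == ChangeCategory.NEVER_FOREST).sum()),
        }


@dataclass
class ScenarioGrid:
    """A land-cover grid together with the scenario that produced it."""

    grid: LandCoverGrid
    tag: str


def classify_forest_change(
    grid_t1: LandCoverGrid, grid_t2: LandCoverGrid
) -> ForestChangeMap:
    """Compare the forest masks of two aligned dates pixel by pixel."""
    require_aligned(grid_t1, grid_t2)
    f1 = grid_t1.class_mask(TargetClass.FOREST)
    f2 = grid_t2.class_mask(TargetClass.FOREST)
    land = grid_t1.land_mask & grid_t2.land_mask
    cats = np.full(grid_t1.shape, ChangeCategory.NODATA, dtype=np.int8)
    cats[land] = ChangeCategory.NEVER_FOREST
    cats[land & f1 & f2] = ChangeCategory.UNCHANGED_FOREST
    cats[land & f1 & ~f2] = ChangeCategory.DEFORESTED
    cats[land & ~f1 & f2] = ChangeCategory.REFORESTED
    return ForestChangeMap(
        cats, grid_t1.cell_size, grid_t1.origin, getattr(grid_t1, "year", None),
        getattr(grid_t2, "year", None),
    )


def build_scenario(change: ForestChangeMap, which: str) -> ScenarioGrid:
    """Build the forest landscape of one scenario from a change map.

    Non-forest land pixels carry the single background code OTHER; the
    focal-class metrics are invariant to background labels.
    """
    if which not in SCENARIO_TAGS:
        raise ValueError(f"unknown scenario tag {which!r}; one of {SCENARIO_TAGS}")
    cc = ChangeCategory
    if which == "TRUE_T1":
        forest = change.mask(cc.UNCHANGED_FOREST) | change.mask(cc.DEFORESTED)
    elif which == "TRUE_T2":
        forest = change.mask(cc.UNCHANGED_FOREST) | change.mask(cc.REFORESTED)
    elif which == "DEFORESTATION_ONLY":
        forest = change.mask(cc.UNCHANGED_FOREST)
    else:  # REFORESTATION_ONLY: union of both dates' forest
        forest = (
            change.mask(cc.UNCHANGED_FOREST)
            | change.mask(cc.DEFORESTED)
            | change.mask(cc.REFORESTED)
        )
    values = np.full(change.categories.shape, -9999, dtype=np.int64)
    values[change.land_mask] = TargetClass.OTHER
    values[forest] = TargetClass.FOREST
    grid = LandCoverGrid(
        values,
        cell_size=change.cell_size,
        nodata=-9999,
        origin=change.origin,
        vocabulary=DEFAULT_VOCABULARY,
    )
    return ScenarioGrid(grid, which)


def apply_urban_mask(
    grid: LandCoverGrid,
    urban_t1: np.ndarray,
    urban_t2: np.ndarray,
    to_nodata: bool = True,
) -> LandCoverGrid:
    """Remove the union of two dates' urban pixels from the landscape.

    With ``to_nodata`` (default) masked pixels leave the landscape
    entirely, shrinking A_T, so forest metrics are computed "outside
    urban areas"; with ``to_nodata=False`` they become background OTHER
    instead (A_T preserved).
    """
    if urban_t1.shape != grid.shape or urban_t2.shape != grid.shape:
        raise ValueError("urban masks must match the grid shape")
    union = urban_t1.astype(bool) | urban_t2.astype(bool)
    values = grid.values.copy()
    values[union] = grid.nodata if to_nodata else TargetClass.OTHER
    return grid.with_values(values)


def mean_distance_to_unchanged(
    change: ForestChangeMap, category: int | str
) -> float:
    """Mean distance (m) from pixels of a change category to unchanged forest.

    Distances are Euclidean, pixel center to nearest unchanged-forest
    pixel center, computed with an exact distance transform seeded on
    the unchanged-forest set. By construction category pixels are never
    unchanged pixels, so no zero distances enter the mean.
    """
    if isinstance(category, str):
        category = {"DEFORESTED": ChangeCategory.DEFORESTED,
                    "REFORESTED": ChangeCategory.REFORESTED}[category.upper()]
    if category not in (ChangeCategory.DEFORESTED, ChangeCategory.REFORESTED):
        raise ValueError("category must be DEFORESTED or REFORESTED")
    unchanged = change.mask(ChangeCategory.UNCHANGED_FOREST)
    sites = change.mask(category)
    if not unchanged.any():
        raise ValueError("no unchanged-forest pixels to measure distance to")
    if not sites.any():
        raise ValueError("no pixels of the requested change category")
    dist = ndimage.distance_transform_edt(
        ~unchanged, sampling=change.cell_size
    )
    return float(dist[sites].mean())


def relative_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("relative change is undefined for a zero reference")
    return 100.0 * (value - reference) / reference
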