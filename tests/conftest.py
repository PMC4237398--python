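"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's vectorized code paths:
patch delineation by explicit flood fill, edge length by exhaustive
face enumeration, distances by all-pairs minimisation. They are slow
and obviously correct, which is the point.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragscape import LandCoverGrid, TargetClass


@pytest.fixture
def grid_factory():
    def make(values, cell_size=30.0, nodata=-9999, origin=(0.0, 0.0)):
        return LandCoverGrid(
            np.asarray(values, dtype=np.int64),
            cell_size=cell_size,
            nodata=nodata,
            origin=origin,
        )

    return make


@pytest.fixture
def random_landcover(grid_factory):
    """Random grids over {FOREST, PASTURE, OTHER} plus optional nodata."""

    def make(shape, seed, p_forest=0.4, p_nodata=0.0, cell_size=30.0):
        rng = np.random.default_rng(seed)
        vals = np.where(
            rng.random(shape) < p_forest, TargetClass.FOREST, TargetClass.PASTURE
        )
        vals = np.where(rng.random(shape) < 0.2, TargetClass.OTHER, vals)
        if p_nodata:
            vals = np.where(rng.random(shape) < p_nodata, -9999, vals)
        return grid_factory(vals, cell_size=cell_size)

    return make


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def flood_fill_patches(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean mask by explicit stack flood fill."""
    nr, nc = mask.shape
    if connectivity == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    patches = []
    for r in range(nr):
        for c in range(nc):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in moves:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2] \
                                and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                patches.append(comp)
    return patches


def count_edge_faces(
    mask: np.ndarray, land: np.ndarray, policy: str, pixels: set
) -> int:
    """Exhaustive 4-face count for one patch under a boundary policy."""
    nr, nc = mask.shape
    faces = 0
    for r, c in pixels:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r2, c2 = r + dr, c + dc
            inside = 0 <= r2 < nr and 0 <= c2 < nc
            if not inside or not land[r2, c2]:
                if policy == "include":
                    faces += 1
                continue
            if not mask[r2, c2]:
                faces += 1
    return faces


def all_pairs_min_distance(
    sources: np.ndarray, targets: np.ndarray, cell_size: float
) -> np.ndarray:
    """For every source pixel, the minimum center distance to a target."""
    sr, sc = np.nonzero(sources)
    tr, tc = np.nonzero(targets)
    d = np.sqrt(
        (sr[:, None] - tr[None, :]) ** 2.0 + (sc[:, None] - tc[None, :]) ** 2.0
    )
    return d.min(axis=1) * cell_size
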