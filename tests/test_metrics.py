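import numpy as np
import pytest

from fragscape import TargetClass, all_class_metrics, class_metrics, label_patches
from conftest import count_edge_faces, flood_fill_patches

F, P, O = TargetClass.FOREST, TargetClass.PASTURE, TargetClass.OTHER


def test_absent_class_yields_zero_patches_and_undefined_metrics(grid_factory):
    g = grid_factory(np.full((5, 5), P))
    ps = label_patches(g, F)
    assert ps.n == 0
    cm = class_metrics(ps)
    assert not cm.defined
    assert np.isnan(cm.area_mn) and np.isnan(cm.ed)


def test_single_interior_pixel_analytics(grid_factory):
    vals = np.full((5, 5), P)
    vals[2, 2] = F
    ps = label_patches(grid_factory(vals), F)
    assert ps.n == 1
    assert ps.patch_area[0] == 900.0
    assert ps.patch_edge[0] == 120.0


def test_two_by_two_block_perimeter(grid_factory):
    vals = np.full((6, 6), P)
    vals[2:4, 2:4] = F
    ps = label_patches(grid_factory(vals), F)
    assert ps.n == 1
    assert ps.patch_edge[0] == 240.0


def test_diagonal_pair_connectivity(grid_factory):
    vals = np.full((4, 4), P)
    vals[1, 1] = vals[2, 2] = F
    assert label_patches(grid_factory(vals), F, connectivity=8).n == 1
    assert label_patches(grid_factory(vals), F, connectivity=4).n == 2


def test_boundary_policy_on_corner_pixel(grid_factory):
    vals = np.full((3, 3), P)
    vals[0, 0] = F
    g = grid_factory(vals)
    assert label_patches(g, F, boundary_policy="exclude").patch_edge[0] == 60.0
    assert label_patches(g, F, boundary_policy="include").patch_edge[0] == 120.0


def test_nodata_faces_follow_policy(grid_factory):
    vals = np.full((3, 3), P)
    vals[1, 1] = F
    vals[0, 1] = -9999
    g = grid_factory(vals)
    assert label_patches(g, F, boundary_policy="exclude").patch_edge[0] == 90.0
    assert label_patches(g, F, boundary_policy="include").patch_edge[0] == 120.0


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("connectivity", [4, 8])
@pytest.mark.parametrize("policy", ["exclude", "include"])
def test_patches_and_edges_match_brute_force(random_landcover, seed, connectivity, policy):
    """Labeling equals flood fill; edges equal exhaustive face counts."""
    g = random_landcover((20, 20), seed=seed, p_nodata=0.1)
    ps = label_patches(g, F, connectivity, policy)
    mask = (g.values == F)
    oracle = flood_fill_patches(mask, connectivity)
    assert ps.n == len(oracle)
    got = {frozenset(zip(*np.nonzero(ps.labels == k + 1))) for k in range(ps.n)}
    want = {frozenset(c) for c in oracle}
    assert got == want
    land = g.land_mask
    by_pixels = {frozenset(c): count_edge_faces(mask, land, policy, c) * 30.0
                 for c in oracle}
    for k in range(ps.n):
        pix = frozenset(zip(*np.nonzero(ps.labels == k + 1)))
        assert ps.patch_edge[k] == by_pixels[pix]


@pytest.mark.parametrize("seed", range(4))
def test_class_metrics_match_direct_resummation(random_landcover, seed):
    """All four indices recomputed independently from the label array."""
    g = random_landcover((30, 30), seed=100 + seed)
    ps = label_patches(g, F)
    cm = class_metrics(ps)
    at = g.land_mask.sum() * 900.0
    areas = np.array([(ps.labels == k + 1).sum() * 900.0 for k in range(ps.n)])
    edges = ps.patch_edge
    assert np.isclose(cm.lpi, 100 * areas.max() / at)
    assert np.isclose(cm.ed, 1e4 * edges.sum() / at)
    assert np.isclose(cm.area_mn, areas.mean() / 1e4)
    assert np.isclose(cm.edge_area, 1e4 * edges.sum() / areas.sum())
    # invariant: AREA_MN * n * 1e4 = sum of patch areas
    assert np.isclose(cm.area_mn * ps.n * 1e4, areas.sum())


def test_full_landscape_lpi_is_100(grid_factory):
    g = grid_factory(np.full((10, 10), F))
    assert class_metrics(label_patches(g, F)).lpi == 100.0


def test_ed_analytic_example(grid_factory):
    # one 900 m^2 patch in a 100x100-pixel, 30 m landscape of 900 ha
    vals = np.full((100, 100), P)
    vals[50, 50] = F
    cm = class_metrics(label_patches(grid_factory(vals), F))
    assert np.isclose(cm.ed, 120.0 / 900.0)
    assert np.isclose(cm.area_mn, 0.09)


def test_checkerboard_symmetry(grid_factory):
    vals = np.indices((8, 8)).sum(0) % 2
    vals = np.where(vals == 0, F, P)
    df = all_class_metrics(grid_factory(vals), [F, P]).set_index("class")
    for col in ("AREA_MN", "ED", "EDGE_AREA", "n_patches"):
        assert df.loc["FOREST", col] == df.loc["PASTURE", col]


def test_all_class_metrics_flags_absent_class(grid_factory):
    df = all_class_metrics(grid_factory(np.full((5, 5), F)), [F, TargetClass.URBAN])
    assert df.set_index("class").loc["FOREST", "defined"]
    assert not df.set_index("class").loc["URBAN", "defined"]


def test_high_density_urban_counts_inside_urban(grid_factory):
    vals = np.full((4, 4), O)
    vals[0, 0] = TargetClass.URBAN
    vals[0, 1] = TargetClass.HIGH_DENSITY_URBAN
    ps = label_patches(grid_factory(vals), TargetClass.URBAN)
    assert ps.n == 1
    assert ps.patch_area[0] == 1800.0


def test_connecting_pixel_merges_never_decreases_lpi(grid_factory):
    vals = np.full((5, 7), P)
    vals[2, 1:3] = F
    vals[2, 4:6] = F
    g = grid_factory(vals)
    before = label_patches(g, F)
    vals2 = vals.copy()
    vals2[2, 3] = F
    after = label_patches(grid_factory(vals2), F)
    assert after.n <= before.n
    assert class_metrics(after).lpi >= class_metrics(before).lpi


def test_ed_invariant_to_background_relabeling(random_landcover, grid_factory):
    g = random_landcover((15, 15), seed=7)
    base = class_metrics(label_patches(g, F)).ed
    swapped = np.where(g.values == P, O, np.where(g.values == O, P, g.values))
    assert class_metrics(label_patches(grid_factory(swapped), F)).ed == base


def test_fragmentation_direction_at_fixed_composition(grid_factory):
    """Scattering a square patch into singles raises ED and EDGE_AREA
    and lowers AREA_MN — the fragmentation direction of the indices."""
    compact = np.full((12, 12), P)
    compact[4:7, 4:7] = F
    scattered = np.full((12, 12), P)
    scattered[::4, ::4] = F  # 9 isolated pixels, same composition
    cmc = class_metrics(label_patches(grid_factory(compact), F))
    cms = class_metrics(label_patches(grid_factory(scattered), F))
    assert cmc.area == cms.area
    assert cms.ed > cmc.ed
    assert cms.edge_area > cmc.edge_area
    assert cms.area_mn < cmc.area_mn
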