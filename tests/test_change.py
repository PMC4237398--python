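import numpy as np
import pytest

from fragscape import (
    ChangeCategory,
    TargetClass,
    apply_urban_mask,
    build_scenario,
    class_metrics,
    classify_forest_change,
    label_patches,
    mean_distance_to_unchanged,
    relative_change,
)
from conftest import all_pairs_min_distance

F, P = TargetClass.FOREST, TargetClass.PASTURE
CC = ChangeCategory


def _pair(vals1, vals2, grid_factory):
    return grid_factory(vals1), grid_factory(vals2)


def test_identical_grids_have_no_change(random_landcover):
    g = random_landcover((10, 10), seed=0)
    ch = classify_forest_change(g, g)
    counts = ch.counts()
    assert counts["deforested"] == 0 and counts["reforested"] == 0


def test_total_loss_is_all_deforested(grid_factory):
    g1, g2 = _pair(np.full((4, 4), F), np.full((4, 4), P), grid_factory)
    ch = classify_forest_change(g1, g2)
    assert ch.counts()["deforested"] == 16
    assert ch.counts()["unchanged_forest"] == 0


def test_single_gain_and_loss_enumerated(grid_factory):
    v1 = np.full((3, 3), P); v1[0, 0] = F; v1[1, 1] = F
    v2 = v1.copy(); v2[0, 0] = P; v2[2, 2] = F
    ch = classify_forest_change(*_pair(v1, v2, grid_factory))
    c = ch.categories
    assert c[0, 0] == CC.DEFORESTED
    assert c[2, 2] == CC.REFORESTED
    assert c[1, 1] == CC.UNCHANGED_FOREST
    assert ch.counts() == {"unchanged_forest": 1, "deforested": 1,
                           "reforested": 1, "never_forest": 6}


def test_misaligned_grids_rejected(grid_factory):
    g1 = grid_factory(np.full((3, 3), F))
    g2 = grid_factory(np.full((3, 3), F), origin=(30.0, 0.0))
    with pytest.raises(ValueError, match="aligned"):
        classify_forest_change(g1, g2)


def test_scenario_set_arithmetic(random_landcover):
    g1 = random_landcover((15, 15), seed=3)
    g2 = random_landcover((15, 15), seed=4)
    ch = classify_forest_change(g1, g2)
    n = ch.counts()
    masks = {tag: build_scenario(ch, tag).grid.class_mask(F)
             for tag in ("TRUE_T1", "TRUE_T2", "DEFORESTATION_ONLY",
                         "REFORESTATION_ONLY")}
    assert masks["DEFORESTATION_ONLY"].sum() == n["unchanged_forest"]
    assert masks["REFORESTATION_ONLY"].sum() == (
        n["unchanged_forest"] + n["deforested"] + n["reforested"]
    )
    assert masks["TRUE_T1"].sum() == n["unchanged_forest"] + n["deforested"]
    # containment chain: ref-only >= t1, t2 >= def-only, pixelwise
    assert (masks["REFORESTATION_ONLY"] >= masks["TRUE_T1"]).all()
    assert (masks["REFORESTATION_ONLY"] >= masks["TRUE_T2"]).all()
    assert (masks["TRUE_T1"] >= masks["DEFORESTATION_ONLY"]).all()
    assert (masks["TRUE_T2"] >= masks["DEFORESTATION_ONLY"]).all()


def test_zero_change_scenarios_coincide(random_landcover):
    g = random_landcover((10, 10), seed=5)
    ch = classify_forest_change(g, g)
    ref = build_scenario(ch, "TRUE_T1").grid.class_mask(F)
    for tag in ("TRUE_T2", "DEFORESTATION_ONLY", "REFORESTATION_ONLY"):
        assert np.array_equal(build_scenario(ch, tag).grid.class_mask(F), ref)


def test_unknown_scenario_tag(random_landcover):
    ch = classify_forest_change(random_landcover((4, 4), 0),
                                random_landcover((4, 4), 0))
    with pytest.raises(ValueError, match="unknown scenario"):
        build_scenario(ch, "NOPE")


def test_empty_urban_mask_leaves_metrics_unchanged(random_landcover):
    g = random_landcover((12, 12), seed=6)
    empty = np.zeros(g.shape, dtype=bool)
    masked = apply_urban_mask(g, empty, empty)
    np.testing.assert_array_equal(masked.values, g.values)


def test_urban_mask_covering_all_forest(random_landcover):
    g = random_landcover((12, 12), seed=7)
    forest = g.class_mask(F)
    masked = apply_urban_mask(g, forest, np.zeros_like(forest))
    assert label_patches(masked, F).n == 0


def test_urban_mask_shrinks_landscape_and_matches_reduced_oracle(random_landcover, grid_factory):
    g = random_landcover((15, 15), seed=8)
    rng = np.random.default_rng(9)
    u1 = rng.random(g.shape) < 0.15
    u2 = rng.random(g.shape) < 0.1
    masked = apply_urban_mask(g, u1, u2)
    # oracle: build the reduced landscape by hand and recompute ED
    reduced = g.values.copy()
    reduced[u1 | u2] = -9999
    oracle = class_metrics(label_patches(grid_factory(reduced), F))
    got = class_metrics(label_patches(masked, F))
    assert np.isclose(got.ed, oracle.ed)
    assert masked.land_mask.sum() == g.land_mask.sum() - (
        (u1 | u2) & g.land_mask
    ).sum()


def test_mean_distance_adjacent_and_diagonal(grid_factory):
    v1 = np.full((3, 3), P)
    v1[0, 0] = F; v1[0, 1] = F; v1[2, 2] = F
    v2 = v1.copy(); v2[0, 1] = P; v2[2, 2] = P  # both lost
    ch = classify_forest_change(*_pair(v1, v2, grid_factory))
    # (0,1) is 4-adjacent (30 m) and (2,2) diagonal x2 (2*30*sqrt(2)) to (0,0)
    expected = (30.0 + 2 * 30.0 * np.sqrt(2)) / 2
    assert np.isclose(mean_distance_to_unchanged(ch, "DEFORESTED"), expected)


@pytest.mark.parametrize("seed", range(3))
def test_mean_distance_matches_all_pairs_brute_force(random_landcover, seed):
    g1 = random_landcover((12, 12), seed=20 + seed)
    g2 = random_landcover((12, 12), seed=40 + seed)
    ch = classify_forest_change(g1, g2)
    n = ch.counts()
    if not (n["unchanged_forest"] and n["reforested"]):
        pytest.skip("degenerate draw")
    oracle = all_pairs_min_distance(
        ch.mask(CC.REFORESTED), ch.mask(CC.UNCHANGED_FOREST), 30.0
    ).mean()
    assert np.isclose(mean_distance_to_unchanged(ch, "REFORESTED"), oracle)


def test_mean_distance_invariant_to_never_forest_relabeling(grid_factory):
    v1 = np.full((6, 6), P); v1[0, :3] = F; v1[5, 5] = F
    v2 = v1.copy(); v2[5, 5] = P
    ch = classify_forest_change(*_pair(v1, v2, grid_factory))
    d1 = mean_distance_to_unchanged(ch, "DEFORESTED")
    v1b = np.where(v1 == P, TargetClass.OTHER, v1)
    v2b = np.where(v2 == P, TargetClass.AGRICULTURE, v2)
    ch2 = classify_forest_change(*_pair(v1b, v2b, grid_factory))
    assert mean_distance_to_unchanged(ch2, "DEFORESTED") == d1


def test_mean_distance_errors_on_empty_sets(grid_factory):
    g = grid_factory(np.full((3, 3), F))
    ch = classify_forest_change(g, g)
    with pytest.raises(ValueError, match="category"):
        mean_distance_to_unchanged(ch, "DEFORESTED")


def test_relative_change_examples():
    # the deforestation-only and reforestation-only mean-patch-area shifts
    assert round(relative_change(8.03, 6.07), 1) == -24.4
    assert round(relative_change(8.03, 10.73), 1) == 33.6
    assert relative_change(5.0, 5.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        relative_change(0.0, 1.0)
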