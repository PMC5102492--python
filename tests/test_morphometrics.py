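"""Compactness, lacunae, skeleton topology and node merging."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull as ScipyHull

from angiosprout import (UndefinedValueError, analyze, compactness,
                         convex_hull, detect_and_merge_nodes, label_lacunae,
                         lacuna_area_sd, largest_connected_component,
                         skeletonize)
from angiosprout.morphometrics import label_components, merge_nodes
from conftest import (brute_force_hull_vertices, flood_fill_components,
                      polygon_area)


def plus_pentomino():
    mask = np.zeros((7, 7), dtype=bool)
    mask[2, 3] = mask[3, 2] = mask[3, 3] = mask[3, 4] = mask[4, 3] = True
    return mask


class TestLargestConnectedComponent:
    def test_single_blob_is_itself(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        comp, area = largest_connected_component(mask)
        assert area == 9 and np.array_equal(comp, mask)

    def test_larger_of_two_blobs_wins(self):
        mask = np.zeros((10, 14), dtype=bool)
        mask[1:4, 1:5] = True  # 12 sites
        mask[6:7, 8:13] = True  # 5 sites
        _, area = largest_connected_component(mask)
        assert area == 12

    def test_diagonal_touch_is_connected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        _, area = largest_connected_component(mask)
        assert area == 2

    def test_empty_mask_explicit_empty_result(self):
        comp, area = largest_connected_component(np.zeros((5, 5), dtype=bool))
        assert area == 0 and not comp.any()

    def test_union_find_matches_flood_fill_on_random_masks(self, rng):
        """Union-find labeling partitions identically to flood fill
        (100 random masks)."""
        for _ in range(100):
            mask = rng.random((12, 12)) < rng.uniform(0.2, 0.7)
            ours = label_components(mask)
            oracle = flood_fill_components(mask)
            # same partition: label images are equal up to renaming
            pairs = {(int(a), int(b))
                     for a, b in zip(ours[mask], oracle[mask])}
            assert len({a for a, _ in pairs}) == len(pairs)
            assert len({b for _, b in pairs}) == len(pairs)


class TestConvexHull:
    def test_single_site_unit_square(self):
        c = compactness(np.array([[1]], dtype=bool))
        assert c == pytest.approx(1.0)

    def test_solid_block_area(self):
        pts = np.array([[0, 0], [4, 0], [0, 3], [4, 3], [2, 1]], dtype=float)
        _, area = convex_hull(pts)
        assert area == pytest.approx(12.0)

    def test_collinear_degenerates_to_zero_area(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        _, area = convex_hull(pts)
        assert area == 0.0

    def test_matches_brute_force_and_scipy_on_random_sets(self, rng):
        """Graham-scan hull equals the half-plane brute force (vertex set)
        and scipy's Qhull (area) on random <=12-point sets."""
        for _ in range(40):
            pts = rng.integers(0, 15, size=(int(rng.integers(4, 13)), 2))
            pts = np.unique(pts, axis=0).astype(float)
            hull, area = convex_hull(pts)
            assert {tuple(p) for p in hull} == brute_force_hull_vertices(pts)
            if len(np.unique(pts, axis=0)) >= 3 and area > 0:
                assert area == pytest.approx(ScipyHull(pts).volume)
            assert area == pytest.approx(polygon_area(hull))


class TestCompactness:
    def test_solid_block_is_one(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        assert compactness(mask) == pytest.approx(1.0)

    def test_plus_pentomino_five_sevenths(self):
        assert compactness(plus_pentomino()) == pytest.approx(5 / 7)

    def test_row_of_three_is_one(self):
        mask = np.zeros((3, 5), dtype=bool)
        mask[1, 1:4] = True
        assert compactness(mask) == pytest.approx(1.0)

    def test_empty_mask_undefined(self):
        with pytest.raises(UndefinedValueError):
            compactness(np.zeros((4, 4), dtype=bool))

    def test_invariant_under_translation_and_rotation(self, rng):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:9, 4:12] = True
        mask[8:15, 6:9] = True
        c0 = compactness(mask)
        assert compactness(np.roll(mask, (3, 2), axis=(0, 1))) == pytest.approx(c0)
        assert compactness(np.rot90(mask)) == pytest.approx(c0)


class TestLacunae:
    def test_solid_block_has_none(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:7, 1:7] = True
        assert label_lacunae(mask) == []

    def test_ring_around_one_site(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        mask[2, 2] = False
        assert label_lacunae(mask) == [1]

    def test_c_shape_open_to_border_is_no_lacuna(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        mask[2, 2] = False
        mask[0:3, 2] = ~mask[0:3, 2] * False  # carve a channel to the border
        mask[0, 2] = False
        mask[1, 2] = False
        assert label_lacunae(mask) == []

    def test_count_invariant_under_hole_preserving_dilation(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:9, 2:9] = True
        mask[4:6, 4:6] = False  # one 4-site lacuna
        assert len(label_lacunae(mask)) == 1
        grown = mask.copy()
        grown[1, 2:9] = True  # dilate outward only
        assert len(label_lacunae(grown)) == 1

    @pytest.mark.parametrize("areas, expected", [
        ([4], 0.0), ([4, 4, 4], 0.0), ([2, 6], 2.0)])
    def test_population_sd(self, areas, expected):
        assert lacuna_area_sd(areas) == pytest.approx(expected)

    def test_sd_undefined_without_lacunae(self):
        with pytest.raises(UndefinedValueError):
            lacuna_area_sd([])


class TestSkeleton:
    def test_straight_bar_two_ends_no_branches(self):
        mask = np.zeros((11, 40), dtype=bool)
        mask[4:7, 3:37] = True  # 3-wide bar
        graph = skeletonize(mask)
        assert graph.n_end_points == 2
        assert graph.n_branch_points == 0
        # single-pixel wide: no 2x2 square survives thinning
        s = graph.skeleton
        assert not (s[:-1, :-1] & s[:-1, 1:] & s[1:, :-1] & s[1:, 1:]).any()

    def test_t_shape_one_branch_three_ends(self):
        mask = np.zeros((40, 46), dtype=bool)
        mask[4:7, 3:43] = True   # horizontal bar
        mask[4:36, 21:24] = True  # stem down from the middle
        graph = skeletonize(mask)
        assert graph.n_branch_points == 1
        assert graph.n_end_points == 3

    def test_empty_mask_empty_skeleton(self):
        graph = skeletonize(np.zeros((6, 6), dtype=bool))
        assert not graph.skeleton.any() and graph.nodes == []

    def test_end_points_have_one_skeleton_neighbor(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:8, 4:26] = True
        mask[5:26, 14:17] = True
        graph = skeletonize(mask)
        s = graph.skeleton.astype(int)
        from scipy.ndimage import convolve
        kernel = np.ones((3, 3), dtype=int)
        kernel[1, 1] = 0
        counts = convolve(s, kernel, mode="constant")
        for node in graph.end_nodes():
            assert all(counts[y, x] == 1 for y, x in node.pixels)

    def test_thinning_preserves_topology(self):
        # a looped morphology: skeleton keeps one component and one hole
        from scipy import ndimage

        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        mask[11:19, 11:19] = False
        graph = skeletonize(mask)
        _, ncomp = ndimage.label(graph.skeleton, np.ones((3, 3)))
        assert ncomp == 1
        holes, nholes = ndimage.label(
            ~graph.skeleton, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        border = set(np.unique(np.concatenate(
            [holes[0], holes[-1], holes[:, 0], holes[:, -1]])))
        assert len(set(np.unique(holes[holes > 0])) - border) == 1


class TestNodeMerging:
    def test_nearby_nodes_replaced_by_mean(self):
        merged = merge_nodes([(0, 0, "end"), (0, 6, "end")])
        assert len(merged) == 1
        assert merged[0].position == (0.0, 3.0)

    def test_distant_nodes_unchanged(self):
        merged = merge_nodes([(0, 0, "end"), (0, 20, "end")])
        assert len(merged) == 2

    def test_single_node_unchanged(self):
        merged = merge_nodes([(5, 5, "end")])
        assert merged[0].position == (5.0, 5.0)

    def test_chained_merge_is_single_linkage(self):
        merged = merge_nodes([(0, 0, "end"), (0, 8, "end"), (0, 16, "end")])
        assert len(merged) == 1  # 0-8 and 8-16 chain even though 0-16 >= 10

    def test_kinds_merge_separately(self):
        merged = merge_nodes([(0, 0, "end"), (0, 4, "branch")])
        assert {m.kind for m in merged} == {"end", "branch"}


def test_full_report_consistency():
    mask = np.zeros((40, 46), dtype=bool)
    mask[4:7, 3:43] = True
    mask[4:36, 21:24] = True
    rep = analyze(mask)
    assert rep.n_lacunae == len(rep.lacuna_areas) == 0
    assert rep.lacuna_area_sd is None
    assert 0 < rep.compactness <= 1
    assert rep.n_end_points == 3 and rep.n_branch_points == 1
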