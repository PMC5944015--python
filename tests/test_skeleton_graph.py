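"""Skeleton, graph construction, pruning, classification and tracking."""

import math

import numpy as np
import pytest

from phenoshoot import segmentation as seg
from phenoshoot import skeleton_graph as sg
from phenoshoot import synthetic_plants as synth
from phenoshoot.errors import (
    EmptyInputError,
    InvalidArgumentError,
    UnsupportedTopologyError,
)


def skeleton_from_pixels(pixels):
    pixels = list(pixels)
    rows = [r for r, _ in pixels]
    cols = [c for _, c in pixels]
    mask = np.zeros((max(rows) + 2, max(cols) + 2), bool)
    for r, c in pixels:
        mask[r, c] = True
    return sg.Skeleton(mask=mask)


class TestSkeletonize:
    def test_wide_bar_reduces_to_central_curve(self):
        mask = np.zeros((120, 40), bool)
        mask[10:110, 10:15] = True
        skel = sg.skeletonize(mask)
        pts = np.argwhere(skel.mask)
        # ~100 px tall curve near the bar's center column
        assert np.ptp(pts[:, 0]) > 85
        assert np.all(np.abs(pts[:, 1] - 12) <= 2.5)
        assert mask[skel.mask].all()

    def test_filled_disk_collapses_to_center(self):
        from skimage.draw import disk as draw_disk

        mask = np.zeros((60, 60), bool)
        rr, cc = draw_disk((30, 30), 20)
        mask[rr, cc] = True
        skel = sg.skeletonize(mask)
        pts = np.argwhere(skel.mask)
        assert np.max(np.hypot(pts[:, 0] - 30, pts[:, 1] - 30)) < 6

    def test_thin_line_unchanged(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 7] = True
        skel = sg.skeletonize(mask)
        assert np.array_equal(skel.mask, mask)

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(EmptyInputError):
            sg.skeletonize(np.zeros((10, 10), bool))
        two = np.zeros((20, 20), bool)
        two[2:5, 2:5] = True
        two[12:15, 12:15] = True
        with pytest.raises(InvalidArgumentError):
            sg.skeletonize(two)

    def test_no_2x2_block(self, day20_frame):
        skel = sg.skeletonize(day20_frame.mask)
        m = skel.mask
        assert not (m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]).any()


class TestGraphFromSkeleton:
    def test_y_shape_nodes_and_edges(self):
        pixels = [(r, 10) for r in range(10, 21)]
        pixels += [(10 - i, 10 - i) for i in range(1, 6)]
        pixels += [(10 - i, 10 + i) for i in range(1, 6)]
        graph = sg.graph_from_skeleton(skeleton_from_pixels(pixels))
        degs = sorted(d for _, d in graph.g.degree)
        assert degs == [1, 1, 1, 3]
        assert graph.g.number_of_edges() == 3

    def test_straight_line_two_nodes_one_edge(self):
        graph = sg.graph_from_skeleton(
            skeleton_from_pixels([(r, 5) for r in range(3, 15)])
        )
        assert len(graph.g) == 2
        assert graph.g.number_of_edges() == 1
        assert not graph.cyclic

    def test_figure_eight_flags_cycle(self):
        pixels = set()
        for i in range(8):  # two diamond loops sharing a pixel
            pixels |= {(10 - i, 10), (10, 10 - i), (10, 10 + i), (10 + i, 10)}
        pixels |= {(2 + i, 10 - 0) for i in range(0)}
        sq = [(2, 10), (10, 2), (18, 10), (10, 18)]
        # build two proper loops: diamond edges
        pix = set()
        for a, b in [((2, 10), (10, 2)), ((10, 2), (18, 10)),
                     ((18, 10), (10, 18)), ((10, 18), (2, 10))]:
            n = max(abs(a[0] - b[0]), abs(a[1] - b[1]))
            for t in range(n + 1):
                pix.add((round(a[0] + (b[0] - a[0]) * t / n),
                         round(a[1] + (b[1] - a[1]) * t / n)))
        graph = sg.graph_from_skeleton(skeleton_from_pixels(pix))
        assert graph.cyclic

    def test_pixel_conservation(self, day20_frame):
        skel = sg.skeletonize(day20_frame.mask)
        graph = sg.graph_from_skeleton(skel)
        covered = set()
        for _, _, _, d in graph.g.edges(keys=True, data=True):
            covered.update(d["path"])
        covered |= set(graph.g.nodes)
        assert covered == skel.pixels


class TestPruneSpurs:
    def _stem_with_branch(self, branch_len):
        pixels = [(r, 20) for r in range(5, 50)]
        pixels += [(30 - 0, 20 + i) for i in range(1, branch_len + 1)]
        return sg.graph_from_skeleton(skeleton_from_pixels(pixels))

    def test_short_branch_removed_and_junction_collapsed(self):
        pruned = sg.prune_spurs(self._stem_with_branch(5), threshold=10)
        assert pruned.g.number_of_edges() == 1
        assert all(d != 2 for _, d in pruned.g.degree)

    def test_long_branch_retained(self):
        pruned = sg.prune_spurs(self._stem_with_branch(11), threshold=10)
        assert pruned.g.number_of_edges() == 3

    def test_no_degree2_nodes_after_pruning(self, day20_graph):
        assert all(d != 2 for _, d in day20_graph.g.degree)

    def test_fixpoint(self, day20_frame):
        raw = sg.graph_from_skeleton(sg.skeletonize(day20_frame.mask))
        once = sg.prune_spurs(raw)
        twice = sg.prune_spurs(once)
        assert sorted(once.g.nodes) == sorted(twice.g.nodes)
        assert once.g.number_of_edges() == twice.g.number_of_edges()

    def test_tree_property(self, day20_graph):
        assert day20_graph.g.number_of_edges() == len(day20_graph.g) - 1


class TestClassify:
    def test_y_plant(self, y_mask):
        graph = sg.mask_to_graph(y_mask)
        assert len(graph.nodes_of_kind(sg.BASE)) == 1
        assert len(graph.nodes_of_kind(sg.JUNCTION)) == 1
        assert len(graph.nodes_of_kind(sg.TIP)) == 2
        assert len(graph.edges_of_kind(sg.LEAF)) == 2
        assert len(graph.edges_of_kind(sg.BASE_SEGMENT)) == 1
        assert sg.count_leaves(graph) == 2

    def test_bare_line_counts_one_leaf(self):
        mask = np.zeros((60, 20), bool)
        mask[10:55, 8:12] = True
        graph = sg.mask_to_graph(mask)
        assert sg.count_leaves(graph) == 1
        assert sg.count_leaves(graph, seedling_counts_leaf=False) == 0

    def test_bottom_tie_breaks_leftmost(self):
        pixels = [(20, c) for c in range(5, 15)]  # horizontal line
        graph = sg.prune_spurs(sg.graph_from_skeleton(skeleton_from_pixels(pixels)))
        typed = sg.classify(graph)
        assert typed.base == (20, 5)

    def test_crossover_cycle_refused(self):
        spec = synth.make_crossover_spec()
        frame = synth.render_frame(spec, 10)
        skel = sg.skeletonize(frame.mask)
        graph = sg.prune_spurs(sg.graph_from_skeleton(skel))
        assert graph.cyclic
        with pytest.raises(UnsupportedTopologyError):
            sg.classify(graph)


class TestStemAndCounts:
    def test_synthetic_junction_recovery(self, plant_spec, day20_graph):
        junctions, path = sg.extract_stem(day20_graph)
        # junctions ordered bottom-to-top
        rows = [r for r, _ in junctions]
        assert rows == sorted(rows, reverse=True)
        # one detected junction per leaf except the topmost (whorl top)
        assert len(junctions) >= len(plant_spec.leaf_specs) - 2
        assert path[0] == day20_graph.base

    def test_y_plant_stem(self, y_mask):
        graph = sg.mask_to_graph(y_mask)
        junctions, path = sg.extract_stem(graph)
        assert len(junctions) == 1

    def test_stem_only_plant(self):
        mask = np.zeros((60, 20), bool)
        mask[10:55, 8:12] = True
        graph = sg.mask_to_graph(mask)
        junctions, path = sg.extract_stem(graph)
        assert junctions == []
        assert len(path) > 30

    def test_leaf_count_matches_truth(self, plant_spec):
        bg = synth.render_background(plant_spec)
        for day in (4, 10, 16, 20):
            frame = synth.render_frame(plant_spec, day)
            graph = sg.mask_to_graph(seg.segment(frame.rgb, bg))
            assert sg.count_leaves(graph) == len(frame.leaf_truth)


@pytest.fixture(scope="module")
def tracked():
    spec = synth.sample_plant_spec(77, n_leaves=5)
    bg = synth.render_background(spec)
    graphs = []
    for day in range(1, 21):
        frame = synth.render_frame(spec, day)
        graphs.append((day, sg.mask_to_graph(seg.segment(frame.rgb, bg))))
    return spec, sg.track_emergence(graphs, radius=35.0)


class TestTrackEmergence:

    def test_ranks_match_emergence_order(self, tracked):
        spec, table = tracked
        first_days = (
            table[~table["missing"]].groupby("leaf_rank")["first_day"].first()
        )
        assert sorted(first_days.index) == list(range(1, 6))
        # ranks ordered by first appearance
        assert list(first_days.sort_index()) == sorted(first_days)
        for rank, leaf in enumerate(spec.leaf_specs, start=1):
            assert abs(first_days[rank] - leaf.emergence_day) <= 1

    def test_ranks_stable_over_days(self, tracked):
        _, table = tracked
        live = table[~table["missing"]]
        # a leaf's junction should not jump around once established
        for rank, sub in live.groupby("leaf_rank"):
            tips = sub.sort_values("day")[["tip_row", "tip_col"]].to_numpy()
            step = np.hypot(*np.diff(tips, axis=0).T)
            assert (step < 40).all()

    def test_single_day_ranks_bottom_up(self, day20_graph):
        table = sg.track_emergence([(20, day20_graph)])
        by_rank = table.sort_values("leaf_rank")
        rows = by_rank["junction_row"].to_numpy()
        assert (np.diff(rows) <= 0).all()

    def test_occlusion_gap_keeps_rank(self, day20_graph):
        table = sg.track_emergence(
            [(1, day20_graph), (3, day20_graph)], radius=20.0
        )
        d1 = table[table["day"] == 1]
        d3 = table[table["day"] == 3]
        assert set(d1["leaf_rank"]) == set(d3["leaf_rank"])
        assert not table["missing"].any()

    def test_missing_day_flagged(self, plant_spec, day20_graph):
        bg = synth.render_background(plant_spec)
        frame5 = synth.render_frame(plant_spec, 5)
        g5 = sg.mask_to_graph(seg.segment(frame5.rgb, bg))
        table = sg.track_emergence([(20, day20_graph), (21, g5)], radius=25.0)
        # leaves present on day 20 but not on the (simulated occluded) later
        # day keep their ranks, flagged missing
        missing = table[(table["day"] == 21) & table["missing"]]
        assert len(missing) > 0
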