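import numpy as np
import pytest

from joverlap.istf import (QueryCounters, build_forest, decide_cutoff_depth,
                           forest_stats, hash_index, lookup_start,
                           query_forest, resolve_start)
from joverlap.segment_tree import (build_segment_tree, query_interval,
                                   tree_stats)

from conftest import check_canonical_invariants, make_intervals, random_spans


def all_uids(ivs):
    return sorted(g.uid for g in ivs)


class TestCutoffDepth:
    def test_synthetic_attachment_profile(self):
        """1000 attachments with 6 at depths 0-3 and 0.5% -> d=3, cut-off 4."""
        # a deep tree whose canonical lists we repopulate with dummies
        tree = build_segment_tree(make_intervals([(i * 10, i * 10 + 4) for i in range(300)]))
        assert tree.height - 1 > 5
        for node in tree.nodes():
            node.canonical.clear()
        dummy = make_intervals([(0, 0)])[0]
        by_depth = {}
        for node in tree.nodes():
            by_depth.setdefault(node.depth, []).append(node)
        for depth, count in [(0, 2), (1, 2), (2, 1), (3, 1)]:
            by_depth[depth][0].canonical.extend([dummy] * count)
        deepest = tree.height - 1
        by_depth[deepest][0].canonical.extend([dummy] * 994)
        tree.n_stored = 1000
        assert sum(tree_stats(tree).attachments_by_depth) == 1000
        assert decide_cutoff_depth(tree, 0.5) == 4  # cum(0..3) = 6 > 5

    def test_all_attachments_at_leaves_clamps_to_leaf_depth(self):
        # adjacent unit intervals: every attachment sits on a point leaf
        tree = build_segment_tree(make_intervals([(i, i) for i in range(32)]))
        assert decide_cutoff_depth(tree, 0.5) == tree.height - 1

    def test_percentage_100_cuts_at_leaf_level(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 50)))
        assert decide_cutoff_depth(tree, 100) == tree.height - 1

    def test_empty_tree_and_bad_percentage_rejected(self):
        with pytest.raises(ValueError):
            decide_cutoff_depth(build_segment_tree([], chrom="c"), 0.5)
        tree = build_segment_tree(make_intervals([(0, 5)]))
        with pytest.raises(ValueError):
            decide_cutoff_depth(tree, 0)


class TestHashIndex:
    @pytest.mark.parametrize("low,preset,expect", [
        (2_345_678, 1_000_000, 2),
        (0, 17, 0),
        (999_999, 1_000_000, 0),
    ])
    def test_floor_division(self, low, preset, expect):
        assert hash_index(low, preset) == expect

    def test_nonpositive_preset_rejected(self):
        with pytest.raises(ValueError):
            hash_index(5, 0)


class TestBuildForest:
    def test_member_intervals_strictly_increasing_and_linked(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            tree = build_segment_tree(make_intervals(random_spans(r, 150)))
            forest = build_forest(tree, 0.5, 1000)
            members = list(forest.members())
            assert members[0] is forest.head and members[-1] is forest.tail
            for a, b in zip(members, members[1:]):
                assert a.node.int_high < b.node.int_low
                assert a.node.int_high + 1 == b.node.int_low  # consecutive
                assert b.prev is a and a.next is b

    def test_members_reachable_from_exactly_one_bucket(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 200)))
        forest = build_forest(tree, 0.5, 500)
        from_buckets = [m for k in forest.bucket_keys for m in forest.buckets[k].nodes]
        assert len(from_buckets) == forest.n_nodes
        assert {id(m) for m in from_buckets} == {id(m) for m in forest.members()}
        for k in forest.bucket_keys:
            for m in forest.buckets[k].nodes:
                assert m.hash_index == k == hash_index(m.node.int_low, forest.preset)

    def test_no_interval_lost_by_cutting(self, rng):
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            ivs = make_intervals(random_spans(r, int(r.integers(1, 150))))
            tree = build_segment_tree(ivs)
            forest = build_forest(tree, 1.0, 750)
            lo = min(g.low for g in ivs)
            hi = max(g.high for g in ivs)
            assert all_uids(query_forest(forest, lo, hi)) == all_uids(ivs)

    def test_spanning_interval_redistributed_without_changing_answers(self, rng):
        ivs = make_intervals([(0, 9_999)] + random_spans(rng, 80, span_max=9_000))
        tree = build_segment_tree(ivs)
        forest = build_forest(tree, 5.0, 512)
        assert forest.moved_attachments >= 1
        for _ in range(50):
            a, b = sorted(int(v) for v in rng.integers(0, 10_000, 2))
            assert all_uids(query_forest(forest, a, b)) == \
                all_uids(query_interval(tree, a, b))
        check_canonical_invariants(tree)  # source tree untouched

    def test_huge_preset_collapses_to_single_bucket(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 60)))
        forest = build_forest(tree, 0.5, 10**9)
        assert forest.bucket_keys == [0]
        assert len(forest.buckets[0].nodes) == forest.n_nodes

    def test_empty_tree_gives_empty_forest(self):
        forest = build_forest(build_segment_tree([], chrom="c"))
        assert forest.head is None and forest.n_nodes == 0
        assert query_forest(forest, 0, 100) == []


class TestLookupStart:
    def build(self, spans, preset):
        tree = build_segment_tree(make_intervals(spans))
        return build_forest(tree, 100, preset)  # cut at leaves: many members

    def test_query_inside_existing_bucket(self):
        forest = self.build([(10, 19), (30, 49)], preset=10)
        node, branch = resolve_start(forest, 12, 14)
        assert branch == "lowIndex"
        assert node.node.int_low <= 12 <= node.node.int_high

    def test_lower_index_fallback(self):
        # all coordinates below 100 -> bucket keys small; query far right
        forest = self.build([(10, 19), (30, 49)], preset=10)
        node, branch = resolve_start(forest, 70, 80)
        assert branch == "lowerIndex"
        assert node is forest.tail

    def test_high_index_path_for_query_left_of_all_nodes(self):
        forest = self.build([(95, 104), (105, 120)], preset=10)
        # lowIndex 0 and no lower bucket; highIndex 9 holds the first member
        node, branch = resolve_start(forest, 5, 97)
        assert branch == "highIndex"
        assert node is forest.head

    def test_higher_index_path(self):
        forest = self.build([(95, 104), (105, 120)], preset=10)
        node, branch = resolve_start(forest, 5, 89)  # highIndex 8 empty, bucket 9+ exists
        assert branch == "higherIndex"

    def test_right_of_all_nodes_yields_no_overlap(self):
        # the cascade backs off to the last lower bucket; the scan then finds
        # nothing, which is the quoted no-overlap outcome
        forest = self.build([(10, 19)], preset=10)
        node, branch = resolve_start(forest, 500, 600)
        assert branch == "lowerIndex" and node is forest.tail
        assert query_forest(forest, 500, 600) == []

    def test_empty_forest_resolves_to_none(self):
        from joverlap.segment_tree import build_segment_tree
        from joverlap.istf import build_forest
        forest = build_forest(build_segment_tree([], chrom="c"))
        assert lookup_start(forest, 0, 10) is None

    def test_wide_query_straddling_all_buckets_still_resolves(self):
        # buckets only strictly between lowIndex and highIndex
        forest = self.build([(45, 54)], preset=10)
        node, branch = resolve_start(forest, 5, 95)
        assert node is forest.head
        assert all_uids(query_forest(forest, 5, 95)) == [(0, 0)]


class TestQueryForest:
    def test_equals_tree_query_on_randomized_fixtures(self):
        for seed in range(25):
            r = np.random.default_rng(seed)
            ivs = make_intervals(random_spans(r, int(r.integers(1, 250))))
            tree = build_segment_tree(ivs)
            for pct, preset in [(0.5, 1000), (5.0, 200), (100, 3000)]:
                forest = build_forest(tree, pct, preset)
                for _ in range(20):
                    a, b = sorted(int(v) for v in r.integers(-200, 11_500, 2))
                    assert all_uids(query_forest(forest, a, b)) == \
                        all_uids(query_interval(tree, a, b)), (seed, pct, preset, a, b)

    def test_point_query_hits_containing_interval(self, rng):
        ivs = make_intervals(random_spans(rng, 100))
        forest = build_forest(build_segment_tree(ivs), 0.5, 700)
        g = ivs[17]
        mid = (g.low + g.high) // 2
        assert g.uid in {h.uid for h in query_forest(forest, mid, mid)}

    def test_at_most_two_nodes_outside_index_range(self):
        worst = 0
        for seed in range(15):
            r = np.random.default_rng(seed)
            ivs = make_intervals(random_spans(r, 200))
            forest = build_forest(build_segment_tree(ivs), 0.5, 400)
            for _ in range(60):
                a, b = sorted(int(v) for v in r.integers(-100, 11_000, 2))
                c = QueryCounters()
                query_forest(forest, a, b, c)
                worst = max(worst, c.outside_index_range)
        assert worst <= 2


class TestForestStats:
    def test_singleton_buckets_have_height_one(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 40)))
        forest = build_forest(tree, 0.5, 1)  # width-1 buckets: all singletons
        stats = forest_stats(forest)
        assert stats.nodes_per_bucket_mean == 1.0
        assert set(stats.bst_heights) == {1}

    def test_bucket_count_monotone_in_preset(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 300)))
        presets = [20, 100, 500, 2500, 12_500]
        counts, means = [], []
        for preset in presets:
            stats = forest_stats(build_forest(tree, 0.5, preset))
            counts.append(stats.bucket_count)
            means.append(stats.nodes_per_bucket_mean)
        assert counts == sorted(counts, reverse=True)
        assert means == sorted(means)

    def test_bst_height_never_exceeds_tree_height(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            tree = build_segment_tree(make_intervals(random_spans(r, 250)))
            for pct in (0.5, 2, 10):
                stats = forest_stats(build_forest(tree, pct, 300))
                assert stats.max_bst_height <= stats.source_height

    def test_moved_count_and_cutoff_monotone_in_percentage(self, rng):
        tree = build_segment_tree(make_intervals(random_spans(rng, 400)))
        moved, cutoffs = [], []
        for pct in (0.5, 1, 2, 5, 10, 50):
            forest = build_forest(tree, pct, 1000)
            moved.append(forest.moved_attachments)
            cutoffs.append(forest.cutoff_depth)
        # larger percentage cuts closer to the leaves (deeper from the root)
        # and forces more attachments to move
        assert moved == sorted(moved)
        assert cutoffs == sorted(cutoffs)
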