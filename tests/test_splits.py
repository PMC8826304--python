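"""Split extraction, RF distance, support frequencies and consensus."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from treeislands import (ArgumentError, majority_rule_consensus, parse_newick,
                         rf_distance, rf_matrix, split_frequencies, tree_splits)
from treeislands.tree_io import TreeSample

from conftest import naive_rf, naive_splits, random_tree


class TestTreeSplits:
    def test_single_cherry_pair(self):
        t = parse_newick("((A,B),(C,D));")
        bps = tree_splits(t)
        assert len(bps) == 1
        (bp,) = bps
        assert set(bp.sides(t.index)[0]) in ({"A", "B"}, {"C", "D"})

    def test_star_tree_has_no_nontrivial_splits(self):
        assert tree_splits(parse_newick("(A,B,C,D,E);")) == frozenset()

    def test_partially_resolved_tree(self):
        t = parse_newick("((A,B),C,(D,E));")
        sides = {frozenset(bp.sides(t.index)[0]) | set() for bp in tree_splits(t)}
        small = {frozenset(min(bp.sides(t.index), key=len)) for bp in tree_splits(t)}
        assert small == {frozenset({"A", "B"}), frozenset({"D", "E"})}
        assert len(sides) == 2

    def test_binary_tree_has_n_minus_3_splits(self):
        for n, seed in [(5, 1), (12, 2), (25, 3)]:
            assert len(tree_splits(random_tree(n, seed))) == n - 3

    def test_fewer_than_four_taxa_rejected(self):
        with pytest.raises(ArgumentError):
            tree_splits(parse_newick("(A,B,C);"))


class TestRFDistance:
    def test_identical_trees_at_distance_zero(self):
        a = random_tree(10, 7)
        b = a.copy()
        assert rf_distance(a, b, normalized=False) == 0
        assert rf_distance(a, b, normalized=True) == 0

    def test_disjoint_four_taxon_trees(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));", index=a.index)
        assert rf_distance(a, b, normalized=False) == 2
        assert rf_distance(a, b, normalized=True) == 1.0

    def test_five_taxon_trees_sharing_one_split(self):
        a = parse_newick("((A,B),C,(D,E));")
        b = parse_newick("((A,C),B,(D,E));", index=a.index)
        assert rf_distance(a, b, normalized=False) == 2
        assert rf_distance(a, b, normalized=True) == 0.5

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_naive_edge_removal_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        a = random_tree(n, seed * 2 + 1)
        b = random_tree(n, seed * 2 + 2)
        assert rf_distance(a, b, normalized=False) == naive_rf(a, b, False)
        assert rf_distance(a, b, normalized=True) == pytest.approx(naive_rf(a, b, True))

    def test_matches_dendropy_symmetric_difference(self):
        import dendropy
        from treeislands import write_newick
        for seed in range(10):
            n = 6 + seed
            a, b = random_tree(n, seed + 100), random_tree(n, seed + 200)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=write_newick(a), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=write_newick(b), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b, normalized=False) == expected

    @pytest.mark.parametrize("seed", range(40))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = random.Random(seed + 999)
        n = rng.randint(5, 20)
        trees = [random_tree(n, seed * 3 + i) for i in range(3)]
        for norm in (False, True):
            d = {(i, j): rf_distance(trees[i], trees[j], normalized=norm)
                 for i, j in itertools.permutations(range(3), 2)}
            for i, j in itertools.combinations(range(3), 2):
                assert d[i, j] == d[j, i]
                assert d[i, j] >= 0
            for i, j, k in itertools.permutations(range(3)):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12
        # identity of indiscernibles at topology level
        same = rf_distance(trees[0], trees[0].copy())
        assert same == 0

    def test_count_bounded_by_twice_internal_edges(self):
        for seed in range(20):
            n = random.Random(seed).randint(4, 15)
            a, b = random_tree(n, seed + 50), random_tree(n, seed + 500)
            assert rf_distance(a, b, normalized=False) <= 2 * (n - 3)
            assert rf_distance(a, b, normalized=True) <= 1.0


class TestRFMatrix:
    def test_identical_trees_give_zero_matrix(self):
        t = random_tree(8, 3)
        sample = TreeSample([t.copy() for _ in range(3)], "x")
        dm = rf_matrix(sample)
        assert np.all(dm.values == 0)

    def test_matrix_equals_pairwise_calls(self):
        trees = [random_tree(7, s) for s in range(6)]
        sample = TreeSample(trees, "x")
        for norm in (True, False):
            dm = rf_matrix(sample, normalized=norm)
            for i in range(6):
                for j in range(6):
                    assert dm.values[i, j] == pytest.approx(
                        rf_distance(trees[i], trees[j], normalized=norm))

    def test_empty_sample_rejected(self):
        with pytest.raises(ArgumentError):
            rf_matrix(TreeSample([], "x"))

    def test_csv_export_square_with_ids(self, tmp_path):
        import pandas as pd
        sample = TreeSample([random_tree(6, s) for s in range(4)], "x")
        dm = rf_matrix(sample)
        path = tmp_path / "rf.csv"
        dm.to_csv(str(path))
        df = pd.read_csv(path, index_col=0)
        assert list(df.columns) == dm.tree_ids
        assert np.allclose(df.values, dm.values)


class TestSplitFrequencies:
    def test_identical_binary_sample_has_n_minus_3_unit_splits(self):
        t = random_tree(9, 4)
        freqs = split_frequencies(TreeSample([t.copy() for _ in range(5)], "x"))
        assert len(freqs) == 9 - 3
        assert all(f == 1.0 for f in freqs.values())

    def test_symmetric_two_tree_sample(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));", index=a.index)
        freqs = split_frequencies(TreeSample([a, b], "x"))
        assert sorted(freqs.values()) == [0.5, 0.5]

    def test_sixty_eight_of_hundred_trees_report_exactly_point_68(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));", index=a.index)
        sample = TreeSample([a.copy() for _ in range(68)] + [b.copy() for _ in range(32)], "x")
        freqs = split_frequencies(sample)
        target = next(iter(a.split_masks()))
        by_mask = {bp.mask: f for bp, f in freqs.items()}
        assert by_mask[target] == 0.68


class TestConsensus:
    def test_repeated_tree_is_its_own_consensus_with_unit_support(self):
        t = random_tree(8, 12)
        cons, supports = majority_rule_consensus(
            TreeSample([t.copy() for _ in range(7)], "x"))
        assert cons == t
        assert len(supports) == 8 - 3
        assert all(s == 1.0 for s in supports.values())

    def test_two_thirds_majority_split_retained(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));", index=a.index)
        cons, supports = majority_rule_consensus(TreeSample([a.copy(), a.copy(), b], "x"))
        assert cons == a
        (sup,) = supports.values()
        assert sup == pytest.approx(2 / 3)

    def test_all_three_resolutions_collapse_to_star(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));", index=a.index)
        c = parse_newick("((A,D),(B,C));", index=a.index)
        cons, supports = majority_rule_consensus(TreeSample([a, b, c], "x"))
        assert supports == {}
        assert cons.split_masks() == frozenset()

    def test_consensus_supports_match_naive_split_counting(self, demo):
        sample, _ = demo
        cons, supports = majority_rule_consensus(sample)
        first = sample.index.labels[0]
        enumerated = [naive_splits(t) for t in sample.trees]
        checked = 0
        for bp, sup in sorted(supports.items(), key=lambda kv: kv[1])[:3]:
            side = frozenset(bp.sides(sample.index)[0])
            if first in side:
                side = frozenset(sample.index.labels) - side
            naive_freq = sum(side in s for s in enumerated) / len(sample)
            assert naive_freq == pytest.approx(sup)
            checked += 1
        assert checked == 3
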