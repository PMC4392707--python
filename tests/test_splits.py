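"""Split extraction, canonical form, and the SD/PD scores."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitdiv import (
    TaxonSet,
    Tree,
    aggregate_trees,
    canonicalize,
    pd_score,
    sd_score,
    separates,
    splits_from_tree,
)
from splitdiv.splits import DegenerateSplitError, SplitSystem
from splitdiv.synth import SynthSpec, gen_tree_collection


class TestCanonicalize:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ((1, 0, 0, 1), (0, 1, 1, 0)),  # complement orientation
            ((0, 1, 1, 0), (0, 1, 1, 0)),  # identity on canonical input
            ((0, 0, 0, 1), (0, 0, 0, 1)),
        ],
    )
    def test_orientation(self, vec, expected):
        assert canonicalize(vec).membership == expected

    @pytest.mark.parametrize("vec", [(1, 1, 1, 1), (0, 0, 0), (1,)])
    def test_degenerate_rejected(self, vec):
        with pytest.raises(DegenerateSplitError):
            canonicalize(vec)

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_complement_invariance(self, vec):
        """canonicalize(complement(sigma)) == canonicalize(sigma), and the
        first position of the canonical form is always 0."""
        if sum(vec) in (0, len(vec)):
            with pytest.raises(DegenerateSplitError):
                canonicalize(vec)
            return
        a = canonicalize(vec)
        b = canonicalize([1 - v for v in vec])
        assert a == b
        assert a.membership[0] == 0
        assert canonicalize(a.membership) == a  # idempotent


class TestSplitsFromTree:
    def test_toy_tree_edge_splits(self, toy_tree, toy_system):
        """One split per unrooted edge; the two root-incident edges merge."""
        assert len(toy_system) == 5
        assert toy_system.total_weight() == pytest.approx(13.0)
        taxa = toy_system.taxa
        ab_cd = canonicalize(
            [0 if lab in ("A", "B") else 1 for lab in taxa.labels]
        )
        assert toy_system.weight_of(ab_cd) == pytest.approx(3.0)  # 1 + 2

    def test_cherry_single_split(self):
        system = splits_from_tree(Tree.from_newick("(A:1,B:2);"))
        assert len(system) == 1
        assert system.total_weight() == pytest.approx(3.0)

    def test_star_trivial_splits(self):
        system = splits_from_tree(Tree.from_newick("(A:1,B:1,C:1);"))
        assert len(system) == 3
        assert all(sp.is_trivial() for sp, _ in system)

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Tree.from_newick("((A:1,A:2):1,B:1);")

    def test_missing_lengths_default_zero(self):
        system = splits_from_tree(Tree.from_newick("((A,B),(C,D));"))
        assert system.total_weight() == 0.0


class TestAggregateTrees:
    def test_identical_trees_mean_is_idempotent(self, toy_tree, toy_system):
        pooled = aggregate_trees([toy_tree, toy_tree], mode="mean")
        assert len(pooled) == len(toy_system)
        for sp, w in toy_system:
            assert pooled.weight_of(sp) == pytest.approx(w, abs=1e-9)

    def test_mean_counts_absent_as_zero(self):
        """Splits missing from a tree contribute 0 to the average."""
        t1 = Tree.from_newick("((A:0,B:2):2,(C:0,D:0):0);")  # AB|CD w=2
        t2 = Tree.from_newick("((A:0,C:0):4,(B:0,D:0):0);")  # AC|BD w=4
        pooled = aggregate_trees([t1, t2], mode="mean")
        taxa = pooled.taxa
        ab = canonicalize([0 if x in "AB" else 1 for x in taxa.labels])
        ac = canonicalize([0 if x in "AC" else 1 for x in taxa.labels])
        assert pooled.weight_of(ab) == pytest.approx(1.0)
        assert pooled.weight_of(ac) == pytest.approx(2.0)

    def test_frequency_mode_bounded(self):
        trees = gen_tree_collection(
            SynthSpec(seed=11, n_taxa=8, n_trees=40, nni_moves=2)
        )
        pooled = aggregate_trees(trees, mode="frequency")
        assert all(0.0 < w <= 1.0 for _sp, w in pooled)

    def test_mismatched_taxa_rejected(self):
        t1 = Tree.from_newick("(A:1,B:1);")
        t2 = Tree.from_newick("(A:1,C:1);")
        with pytest.raises(ValueError, match="'B', 'C'"):
            aggregate_trees([t1, t2])

    def test_sum_mode_unnormalized(self, toy_tree):
        pooled = aggregate_trees([toy_tree, toy_tree], mode="sum")
        assert pooled.total_weight() == pytest.approx(26.0)


class TestScores:
    @pytest.mark.parametrize(
        "subset, expect",
        [({"A", "C"}, True), ({"A", "B"}, False), ({"A"}, False)],
    )
    def test_separates(self, toy_system, subset, expect):
        taxa = toy_system.taxa
        ab_cd = canonicalize([0 if x in "AB" else 1 for x in taxa.labels])
        if subset == {"A"}:
            sp = canonicalize([1 if x == "A" else 0 for x in taxa.labels])
            assert separates(sp, taxa.indices(subset)) is expect
        else:
            assert separates(ab_cd, taxa.indices(subset)) is expect

    @pytest.mark.parametrize(
        "subset, expected",
        [(("A", "B"), 3.0), (("A", "C"), 7.0), (("A", "B", "C", "D"), 13.0)],
    )
    def test_sd_matches_hand_pd(self, toy_system, subset, expected):
        assert sd_score(
            toy_system, toy_system.taxa.indices(subset)
        ) == pytest.approx(expected)

    def test_sd_of_empty_and_singleton_is_zero(self, toy_system):
        assert sd_score(toy_system, []) == 0.0
        assert sd_score(toy_system, [0]) == 0.0

    def test_pd_toy_values(self, toy_tree):
        taxa = toy_tree.taxa
        assert pd_score(toy_tree, taxa.indices(["A", "C"])) == pytest.approx(7.0)
        assert pd_score(toy_tree, range(4)) == pytest.approx(13.0)

    def test_pd_singleton_is_zero_with_warning(self, toy_tree):
        with pytest.warns(UserWarning):
            assert pd_score(toy_tree, [0]) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_pd_equals_sd_exhaustively(self, seed):
        """On random trees, PD (independent Steiner-path computation) equals
        SD of the tree's split system for every subset of size >= 2."""
        tree = gen_tree_collection(
            SynthSpec(seed=seed, n_taxa=4 + seed % 4, n_trees=1,
                      nni_moves=0, length_jitter_sigma=0.0)
        )[0]
        system = splits_from_tree(tree)
        n = tree.taxa.n
        for r in range(2, n + 1):
            for subset in itertools.combinations(range(n), r):
                assert pd_score(tree, subset) == pytest.approx(
                    sd_score(system, subset), abs=1e-9
                )

    def test_sd_monotone_in_subset(self, toy_system):
        n = toy_system.taxa.n
        for r in range(n):
            for s in itertools.combinations(range(n), r):
                for extra in set(range(n)) - set(s):
                    assert sd_score(toy_system, s) <= sd_score(
                        toy_system, set(s) | {extra}
                    ) + 1e-12

    def test_full_set_equals_total_weight(self, toy_system):
        assert sd_score(toy_system, range(4)) == pytest.approx(
            toy_system.total_weight()
        )


class TestTaxonSet:
    def test_rejects_duplicates_and_empties(self):
        with pytest.raises(ValueError):
            TaxonSet(["A", "A"])
        with pytest.raises(ValueError):
            TaxonSet(["A", ""])
        with pytest.raises(ValueError):
            TaxonSet([])

    def test_negative_weight_rejected(self):
        system = SplitSystem(TaxonSet(["A", "B"]))
        with pytest.raises(ValueError, match="negative"):
            system.add([0, 1], -1.0)
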