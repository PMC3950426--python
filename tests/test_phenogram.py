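from __future__ import annotations

import numpy as np
import pytest

from motupipe.delimit import MOTUPartition, threshold_motus
from motupipe.distances import DistanceMatrix
from motupipe.phenogram import condense, neighbor_joining, render_text, to_newick

from conftest import matrix_from_rows, random_rows
from oracles import normalize_splits, random_additive_matrix, tree_splits


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"L{i}" for i in range(len(values))]
    return DistanceMatrix(
        ids=ids, values=values, n_sites=np.full(values.shape, 600, dtype=int)
    )


def _path_lengths(tree):
    """Leaf-to-leaf path lengths via the tip-to-tip distance matrix."""
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b] for a in dm.ids for b in dm.ids if a != b}


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        # For 3 leaves branch lengths are determined exactly:
        # la = (dab + dac - dbc)/2 etc.
        D = _dm([[0, 6, 8], [6, 0, 10], [8, 10, 0]], ids=["a", "b", "c"])
        tree = neighbor_joining(D)
        paths = _path_lengths(tree)
        assert paths[frozenset(("a", "b"))] == pytest.approx(6)
        assert paths[frozenset(("a", "c"))] == pytest.approx(8)
        assert paths[frozenset(("b", "c"))] == pytest.approx(10)

    @pytest.mark.parametrize("trial", range(20))
    def test_recovers_random_additive_trees(self, trial):
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(6, 11))
        values, true_splits = random_additive_matrix(n, rng)
        tree = neighbor_joining(_dm(values))
        # exact path lengths
        paths = _path_lengths(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert paths[frozenset((f"L{i}", f"L{j}"))] == pytest.approx(
                    values[i, j], abs=1e-9
                )
        # exact unrooted topology
        assert tree_splits(tree, n) == normalize_splits(true_splits, n)

    def test_scaling_distances_scales_branch_lengths(self, rng):
        values, _ = random_additive_matrix(7, rng)
        p1 = _path_lengths(neighbor_joining(_dm(values)))
        p2 = _path_lengths(neighbor_joining(_dm(values * 2.0)))
        for pair, length in p1.items():
            assert p2[pair] == pytest.approx(2.0 * length, abs=1e-9)

    def test_leaf_relabelling_gives_isomorphic_tree(self, rng):
        values, _ = random_additive_matrix(8, rng)
        perm = rng.permutation(8)
        t1 = neighbor_joining(_dm(values))
        t2 = neighbor_joining(
            _dm(values[np.ix_(perm, perm)], ids=[f"L{i}" for i in perm])
        )
        assert tree_splits(t1, 8) == tree_splits(t2, 8)
        p1, p2 = _path_lengths(t1), _path_lengths(t2)
        for pair, length in p1.items():
            assert p2[pair] == pytest.approx(length, abs=1e-9)

    def test_no_negative_branch_lengths(self, rng):
        # non-additive random matrix exercises the clamp
        rows = random_rows(rng, n=10, length=120)
        D = matrix_from_rows(rows)
        tree = neighbor_joining(D)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0

    def test_fewer_than_three_leaves_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(_dm([[0, 1], [1, 0]]))

    def test_agrees_with_independent_nj_implementation(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        values, _ = random_additive_matrix(9, rng)
        values = (values + values.T) / 2.0  # shave float asymmetry from path sums
        ids = [f"L{i}" for i in range(9)]
        ours = neighbor_joining(_dm(values, ids=ids))
        theirs = skbio_nj(SkbioDM(values, ids=ids))
        assert tree_splits(ours, 9) == tree_splits(theirs, 9)


class TestCondense:
    def _setup(self, rng):
        # two tight clusters far apart plus one singleton
        base = np.array(
            [
                [0.0, 0.5, 15, 15, 30],
                [0.5, 0.0, 15, 15, 30],
                [15, 15, 0.0, 0.8, 30],
                [15, 15, 0.8, 0.0, 30],
                [30, 30, 30, 30, 0.0],
            ]
        )
        ids = ["a1", "a2", "b1", "b2", "c1"]
        D = _dm(base, ids=ids)
        tree = neighbor_joining(D)
        partition = threshold_motus(D)
        return D, tree, partition

    def test_collapses_groups_with_counts_and_variation(self, rng):
        D, tree, partition = self._setup(rng)
        ct = condense(tree, partition, D=D)
        assert ct.non_monophyletic == []
        assert sorted(c.n for c in ct.clades) == [1, 2, 2]
        by_n = {c.n: c for c in ct.clades if c.n == 1}
        assert by_n[1].variation is None
        assert "n/a" in by_n[1].display_label
        two = [c for c in ct.clades if c.n == 2]
        assert {round(c.variation, 1) for c in two} == {0.5, 0.8}
        # condensed tree has exactly one leaf per group
        assert sum(1 for _ in ct.tree.tips()) == 3

    def test_display_label_contains_locality(self, rng):
        from motupipe.io_metadata import SpecimenRecord

        D, tree, partition = self._setup(rng)
        recs = [
            SpecimenRecord(i, "Trimma alpha", loc)
            for i, loc in zip(D.ids, ["Palau", "Palau", "Fiji", "Fiji", "Rabaul"])
        ]
        ct = condense(tree, partition, D=D, records=recs)
        labels = [c.display_label for c in ct.clades]
        assert any("Palau" in lab and "(2, 0.5%)" in lab for lab in labels)

    def test_non_monophyletic_group_is_flagged_not_collapsed(self, rng):
        D, tree, _ = self._setup(rng)
        # deliberately wrong grouping: one member from each cluster
        bad = MOTUPartition(
            groups={"X": ["a1", "b1"], "Y": ["a2", "b2"], "Z": ["c1"]},
            threshold=2.0,
        )
        ct = condense(tree, bad, D=D)
        assert set(ct.non_monophyletic) == {"X", "Y"}
        # the tree keeps the original leaves of uncollapsed groups
        tips = {t.name for t in ct.tree.tips()}
        assert {"a1", "b1", "a2", "b2"} <= tips

    def test_unrooted_monophyly_across_the_root(self, rng):
        # a group that is a complement-clade in the rooted representation
        # must still be considered monophyletic
        values, _ = random_additive_matrix(6, rng)
        ids = [f"L{i}" for i in range(6)]
        tree = neighbor_joining(_dm(values, ids=ids))
        root_sides = [frozenset(ch.subset()) | ({ch.name} - {None}) for ch in tree.children]
        side = max(root_sides, key=len)
        complement = set(ids) - set(side)
        if len(complement) >= 2:
            part = MOTUPartition(
                groups={
                    "comp": sorted(complement),
                    **{f"s_{i}": [i] for i in sorted(side)},
                },
                threshold=2.0,
            )
            ct = condense(tree, part)
            assert "comp" not in ct.non_monophyletic

    def test_partition_tree_mismatch_errors(self, rng):
        D, tree, partition = self._setup(rng)
        bad = MOTUPartition(groups={"G": ["zz"]}, threshold=2.0)
        with pytest.raises(ValueError, match="leaves"):
            condense(tree, bad)

    def test_newick_and_text_render(self, rng):
        D, tree, partition = self._setup(rng)
        ct = condense(tree, partition, D=D)
        nwk = ct.to_newick()
        assert nwk.endswith(";")
        txt = render_text(ct)
        assert "|" in txt
        assert to_newick(tree).endswith(";")
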