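"""K2P distances, neighbor joining, bootstrap supports, Newick I/O,
progressive alignment."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from planktag import phylo


class TestK2P:
    def test_identical_rows(self):
        assert phylo.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_spot_check(self):
        # 100 columns: 10 transitions (A->G), 5 transversions (A->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert phylo.k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(10):
            a = rng.choice(bases, size=200).tobytes().decode()
            b = rng.choice(bases, size=200).tobytes().decode()
            assert phylo.k2p_distance(a, b) == phylo.k2p_distance(b, a)

    def test_gap_columns_excluded(self):
        # gap column is ignored; remaining columns identical
        assert phylo.k2p_distance("AC-T", "ACGT") == 0.0

    def test_saturation_flagged_maximum(self):
        a = "A" * 10
        b = "C" * 10  # Q = 1: 1 - 2Q < 0
        assert phylo.k2p_distance(a, b) == phylo.SATURATION_DISTANCE

    def test_small_distance_additive_approximation(self):
        # for tiny P, Q the distance approaches P + Q
        a = "A" * 1000
        b = "G" * 2 + "C" * 1 + "A" * 997  # P=0.002, Q=0.001
        assert phylo.k2p_distance(a, b) == pytest.approx(0.003, rel=0.01)


def _tree_path_distance(tree, a, b):
    return tree.find(a).distance(tree.find(b))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        dm = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = phylo.nj_tree(dm, ids)
        for i in range(3):
            for j in range(i + 1, 3):
                assert _tree_path_distance(tree, ids[i], ids[j]) == pytest.approx(
                    dm[i, j], abs=1e-9
                )

    def test_additive_four_taxon_matrix_recovered(self):
        # distances from the tree ((a:1,b:2):1,(c:3,d:4):1)
        ids = ["a", "b", "c", "d"]
        dm = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            dtype=float,
        )
        tree = phylo.nj_tree(dm, ids)
        for i in range(4):
            for j in range(i + 1, 4):
                assert _tree_path_distance(tree, ids[i], ids[j]) == pytest.approx(
                    dm[i, j], abs=1e-9
                )
        # correct quartet topology: ab|cd
        assert phylo.tree_splits(tree) == {frozenset({"a", "b"})}

    def test_additive_random_tree_exact(self):
        """NJ reproduces path distances of random additive matrices."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            # random caterpillar tree over 6 leaves with random lengths
            n = 6
            ids = [f"t{i}" for i in range(n)]
            # build additive matrix from a random tree using skbio via
            # random coordinates: instead, construct from a chain topology
            pos = np.cumsum(rng.uniform(0.1, 1.0, size=n))
            leaf_stem = rng.uniform(0.1, 1.0, size=n)
            dm = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = abs(pos[i] - pos[j]) + leaf_stem[i] + leaf_stem[j]
                    dm[i, j] = dm[j, i] = d
            tree = phylo.nj_tree(dm, ids)
            for i in range(n):
                for j in range(i + 1, n):
                    assert _tree_path_distance(
                        tree, ids[i], ids[j]
                    ) == pytest.approx(dm[i, j], abs=1e-9)

    def test_matches_skbio_topology(self):
        """Independent cross-check against scikit-bio's NJ."""
        rng = np.random.default_rng(12)
        n = 7
        ids = [f"t{i}" for i in range(n)]
        pos = np.cumsum(rng.uniform(0.2, 1.0, size=n))
        stem = rng.uniform(0.1, 2.0, size=n)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = abs(pos[i] - pos[j]) + stem[i] + stem[j]
        ours = phylo.tree_splits(phylo.nj_tree(dm, ids))
        theirs = phylo.tree_splits(skbio_nj(DistanceMatrix(dm, ids)))
        assert ours == theirs

    def test_label_order_invariance(self):
        ids = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.uniform(0.2, 1.0, size=5))
        stem = rng.uniform(0.1, 1.0, size=5)
        dm = np.zeros((5, 5))
        for i in range(5):
            for j in range(i + 1, 5):
                dm[i, j] = dm[j, i] = abs(pos[i] - pos[j]) + stem[i] + stem[j]
        perm = [3, 1, 4, 0, 2]
        dm_p = dm[np.ix_(perm, perm)]
        ids_p = [ids[k] for k in perm]
        assert phylo.tree_splits(phylo.nj_tree(dm, ids)) == phylo.tree_splits(
            phylo.nj_tree(dm_p, ids_p)
        )

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(np.array([[0, 1], [1, 0]], dtype=float), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(bad, ["a", "b", "c"])


def _two_clade_alignment():
    rng = np.random.default_rng(6)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    core = rng.choice(bases, size=200)
    clade2 = core.copy()
    idx = rng.choice(200, size=40, replace=False)  # many diagnostic columns
    for i in idx:
        clade2[i] = bases[(np.where(bases == clade2[i])[0][0] + 1) % 4]

    def noisy(seq, k):
        out = seq.copy()
        pos = rng.choice(200, size=k, replace=False)
        for i in pos:
            out[i] = bases[(np.where(bases == out[i])[0][0] + 2) % 4]
        return out

    rows = tuple(
        s.tobytes().decode()
        for s in (noisy(core, 2), noisy(core, 2), noisy(clade2, 2), noisy(clade2, 2))
    )
    return phylo.AlignedBlock(ids=("a1", "a2", "b1", "b2"), rows=rows)


class TestBootstrap:
    def test_clear_split_gets_high_support(self):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap_support(aln, n_replicates=100, seed=4)
        (node,) = [
            n for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        ]
        assert node.support >= 0.95

    def test_single_replicate_supports_binary(self):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap_support(aln, n_replicates=1, seed=9)
        for n in tree.non_tips(include_self=False):
            if getattr(n, "support", None) is not None:
                assert n.support in (0.0, 1.0)

    def test_seeded_determinism(self):
        aln = _two_clade_alignment()
        t1 = phylo.bootstrap_support(aln, n_replicates=25, seed=13)
        t2 = phylo.bootstrap_support(aln, n_replicates=25, seed=13)
        assert str(t1) == str(t2)

    def test_three_rows_unannotated(self):
        aln = phylo.AlignedBlock(
            ids=("a", "b", "c"),
            rows=("ACGTACGT", "ACGAACGT", "ACGTACCT"),
        )
        tree = phylo.bootstrap_support(aln, n_replicates=10, seed=1)
        assert all(
            getattr(n, "support", None) is None
            for n in tree.non_tips(include_self=False)
        )


class TestNewick:
    def test_three_leaf_round_trip(self, tmp_path):
        dm = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = phylo.nj_tree(dm, ["a", "b", "c"])
        p = tmp_path / "t.nwk"
        phylo.write_newick(tree, p)
        back = phylo.read_newick(p)
        assert {t.name for t in back.tips()} == {"a", "b", "c"}
        for name in "abc":
            assert back.find(name).length == pytest.approx(
                tree.find(name).length, abs=1e-9
            )

    def test_supports_round_trip(self, tmp_path):
        aln = _two_clade_alignment()
        tree = phylo.bootstrap_support(aln, n_replicates=20, seed=2)
        p = tmp_path / "t.nwk"
        phylo.write_newick(tree, p)
        back = phylo.read_newick(p)
        back.assign_supports()
        orig = sorted(
            n.support for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        parsed = sorted(
            n.support for n in back.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        )
        assert parsed == orig


class TestAlignRepresentatives:
    def test_identical_sequences_ungapped(self):
        aln = phylo.align_representatives(
            [("x", "ACGTACGT"), ("y", "ACGTACGT"), ("z", "ACGTACGT")]
        )
        assert all("-" not in row for row in aln.rows)
        assert aln.n_cols == 8

    def test_single_deletion_places_gap(self):
        aln = phylo.align_representatives(
            [("x", "ACGTACGTAC"), ("y", "ACGTCGTAC")]
        )
        rows = dict(zip(aln.ids, aln.rows))
        assert rows["x"] == "ACGTACGTAC"
        assert rows["y"].count("-") == 1
        assert rows["y"].replace("-", "") == "ACGTCGTAC"

    def test_column_count_at_least_longest(self):
        seqs = [("a", "ACGT" * 30), ("b", "ACGT" * 25 + "AA"), ("c", "AC" * 50)]
        aln = phylo.align_representatives(seqs)
        assert aln.n_cols >= max(len(s) for _, s in seqs)
        for (sid, s), row in zip(seqs, [dict(zip(aln.ids, aln.rows))[i] for i, _ in seqs]):
            assert row.replace("-", "") == s

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phylo.align_representatives([])
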