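"""Clustering, pairwise identity, diversity indices, rarefaction, Eq.-style
relative change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planktag import io as pio
from planktag import otu, simulate


def _infix_edit_distance(query: str, target: str) -> int:
    """Independent full-DP oracle: minimal semi-global edit distance of
    `query` placed anywhere inside `target` (free target end gaps)."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            sub = prev[j - 1] + (query[i - 1] != target[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def _oracle_identity(a: str, b: str) -> float:
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    return 1.0 - _infix_edit_distance(q, t) / len(q)


class TestPairwiseIdentity:
    def test_identical(self):
        assert otu.pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_three_quarters(self):
        assert otu.pairwise_identity("ACGT", "ACGA") == 0.75

    def test_symmetric_and_matches_dp_oracle(self):
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(20):
            a = rng.choice(bases, size=300).tobytes().decode()
            b_arr = rng.choice(bases, size=int(rng.integers(150, 300)))
            b = b_arr.tobytes().decode()
            got = otu.pairwise_identity(a, b)
            assert got == otu.pairwise_identity(b, a)
            assert got == pytest.approx(_oracle_identity(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            otu.pairwise_identity("", "ACGT")


class TestClusterGreedy:
    def test_identical_reads_one_otu(self):
        reads = [pio.RawRead(f"r{i}", "ACGT" * 120) for i in range(5)]
        otus = otu.cluster_greedy(reads)
        assert len(otus) == 1
        assert otus[0].size == 5

    def test_divergent_pair_two_otus(self):
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        a = rng.choice(bases, size=200)
        b = a.copy()
        idx = rng.choice(200, size=20, replace=False)  # 90% identity
        for i in idx:
            b[i] = bases[(np.where(bases == b[i])[0][0] + 1) % 4]
        reads = [pio.RawRead("a", a.tobytes().decode()),
                 pio.RawRead("b", b.tobytes().decode())]
        assert len(otu.cluster_greedy(reads, 0.97)) == 2

    def _well_separated_reads(self, n_reads=60, seed=21):
        db = simulate.generate_reference_db(3, 1, 1, seed=seed)
        scheme = simulate.default_tag_scheme(["A"], seed=seed)
        comm = simulate.CommunityProfile(
            sample_id="A",
            taxa=tuple((r.ref_id, 1 / 3) for r in db),
        )
        reads, truth = simulate.generate_reads(
            comm, db, scheme, n_reads, error_rate=0.005,
            length_model=simulate.LengthModel(full_fraction=1.0),
            seed=seed,
        )
        by_sample, _ = pio.demultiplex([pio.RawRead(*r) for r in reads], scheme)
        return by_sample["A"].reads, truth

    def test_recovers_templates_and_matches_single_linkage_oracle(self):
        """Greedy 97% clustering on well-separated templates equals the
        brute-force single-linkage components at the same threshold."""
        reads, truth = self._well_separated_reads()
        otus = otu.cluster_greedy(reads, 0.97)
        assert len(otus) == 3

        # brute-force single-linkage components
        ids = [r.read_id for r in reads]
        seqs = {r.read_id: r.sequence for r in reads}
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        n = len(ids)
        rows, cols = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if otu.pairwise_identity(seqs[ids[i]], seqs[ids[j]]) >= 0.97:
                    rows += [i, j]
                    cols += [j, i]
        graph = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        assert n_comp == len(otus)
        oracle = {}
        for rid, lab in zip(ids, labels):
            oracle.setdefault(lab, set()).add(rid)
        greedy = {frozenset(o.members) for o in otus}
        assert {frozenset(v) for v in oracle.values()} == greedy

        # memberships agree with the generator truth table
        truth_map = dict(zip(truth["read_id"], truth["ref_id"]))
        for o in otus:
            assert len({truth_map[m] for m in o.members}) == 1

    def test_label_permutation_invariance(self):
        reads, _ = self._well_separated_reads(n_reads=30, seed=5)
        relabeled = [
            pio.RawRead(f"z{i:03d}", r.sequence)
            for i, r in enumerate(reversed(reads))
        ]
        assert len(otu.cluster_greedy(reads)) == len(otu.cluster_greedy(relabeled))

    def test_representative_needs_400nt(self):
        short = [pio.RawRead("s1", "ACGT" * 50)] * 1  # 200 nt
        otus = otu.cluster_greedy(short)
        assert otus[0].representative_id is None
        long = [pio.RawRead("l1", "ACGT" * 120)]
        assert otu.cluster_greedy(long)[0].representative_id == "l1"


class TestValidateTaxa:
    def _otus(self, sizes):
        return [
            otu.OTU(otu_id=f"o{i}", centroid_id=f"c{i}",
                    members=[f"m{i}_{k}" for k in range(s)])
            for i, s in enumerate(sizes)
        ]

    def test_three_read_rule(self):
        validated, rejected = otu.validate_taxa(self._otus([5, 3, 2, 1]))
        assert [o.size for o in validated] == [5, 3]
        assert [o.size for o in rejected] == [2, 1]

    def test_min_one_is_identity(self):
        otus = self._otus([2, 1])
        validated, rejected = otu.validate_taxa(otus, min_reads=1)
        assert validated == otus and rejected == []

    def test_partition(self):
        otus = self._otus([4, 3, 2, 1, 1])
        validated, rejected = otu.validate_taxa(otus)
        assert sorted(o.otu_id for o in validated + rejected) == sorted(
            o.otu_id for o in otus
        )


class TestChao1:
    def test_worked_example(self):
        av = otu.AbundanceVector("s", (1, 1, 2, 3))
        assert otu.chao1(av) == 5.0

    def test_no_singletons(self):
        assert otu.chao1(otu.AbundanceVector("s", (2, 5, 9))) == 3.0

    def test_all_singletons_degenerate(self):
        det = otu.chao1_detail(otu.AbundanceVector("s", (1, 1, 1)))
        assert det.value == 6.0 and det.degenerate

    def test_classic_doubleton_variant(self):
        av = otu.AbundanceVector("s", (1, 1, 2, 3))
        # classic n2 counts exact doubletons only (here 1)
        assert otu.chao1(av, classic_n2=True) == 4 + 4 / 2

    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=40).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_never_below_observed_richness(self, counts):
        av = otu.AbundanceVector("s", tuple(counts))
        assert otu.chao1(av) >= av.S


class TestIndices:
    def test_single_otu(self):
        av = otu.AbundanceVector("s", (7,))
        assert otu.shannon(av) == 0.0
        assert otu.simpson(av) == 0.0

    def test_uniform_closed_form(self):
        av = otu.AbundanceVector("s", (5, 5, 5, 5))
        assert otu.shannon(av) == pytest.approx(math.log(4))
        assert otu.simpson(av) == pytest.approx(0.75)

    def test_margalef_example(self):
        av = otu.AbundanceVector("s", (91,) + (1,) * 9)  # S=10, N=100
        assert otu.margalef(av) == pytest.approx(9 / math.log(100))

    def test_margalef_degenerate(self):
        assert otu.margalef(otu.AbundanceVector("s", (1,))) == 0.0

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(4)
        uniform = otu.AbundanceVector("s", (10,) * 8)
        h_max = otu.shannon(uniform)
        for _ in range(50):
            counts = rng.integers(1, 30, size=8)
            if len(set(counts)) == 1:
                continue
            assert otu.shannon(otu.AbundanceVector("s", tuple(counts))) < h_max + 1e-12

    def test_simpson_variants(self):
        av = otu.AbundanceVector("s", (2, 2))
        assert otu.simpson(av, "gini") == pytest.approx(0.5)
        assert otu.simpson(av, "dominance") == pytest.approx(0.5)
        assert otu.simpson(av, "unbiased") == pytest.approx(1 - 2 * 2 / (4 * 3))


class TestRarefaction:
    def test_full_depth_gives_S(self):
        av = otu.AbundanceVector("s", (5, 3, 1))
        ((_, s),) = otu.rarefaction_curve(av, [av.N])
        assert s == pytest.approx(av.S)

    def test_two_doubletons_depth_one(self):
        av = otu.AbundanceVector("s", (2, 2))
        ((_, s),) = otu.rarefaction_curve(av, [1])
        assert s == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_analytic(self):
        av = otu.AbundanceVector("s", (5, 3, 1))
        ((_, exp),) = otu.rarefaction_curve(av, [4])
        reps = 1000
        ((_, mc),) = otu.rarefaction_curve(
            av, [4], mode="monte-carlo", n_reps=reps, seed=11
        )
        # per-draw variance of the observed-OTU count is at most S^2/4
        se = av.S / (2 * math.sqrt(reps))
        assert abs(mc - exp) <= 3 * se

    def test_monotone_in_depth(self):
        av = otu.AbundanceVector("s", (8, 4, 2, 1, 1))
        curve = otu.rarefaction_curve(av, list(range(1, av.N + 1)))
        values = [v for _, v in curve]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))

    def test_depth_beyond_total_rejected(self):
        av = otu.AbundanceVector("s", (2, 2))
        with pytest.raises(ValueError):
            otu.rarefaction_curve(av, [5])


class TestRelativeChange:
    def test_haptophyceae_worked_example(self):
        rc = otu.relative_change(660, 5435, 18280, 41057)
        assert rc.R == pytest.approx(3.666, abs=5e-4)
        assert round(rc.R, 1) == 3.7

    def test_equal_proportions(self):
        assert otu.relative_change(10, 20, 100, 200).R == pytest.approx(1.0)

    def test_reciprocal_identity(self):
        f = otu.relative_change(7, 13, 110, 90).R
        b = otu.relative_change(13, 7, 90, 110).R
        assert f * b == pytest.approx(1.0)

    def test_new_and_lost_flags(self):
        assert otu.relative_change(0, 5, 100, 100).status == "new"
        lost = otu.relative_change(5, 0, 100, 100)
        assert lost.status == "lost" and lost.R == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            otu.relative_change(-1, 5, 100, 100)
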