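"""Distance phylogenetics for the focal-group representatives.

Kimura two-parameter (K2P) distances with pairwise gap deletion,
Saitou-Nei neighbor-joining, bipartition bootstrap supports from column
resampling, Newick round-tripping (scikit-bio TreeNode), and a
deterministic center-star progressive aligner standing in for an
external multiple-alignment tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from skbio import TreeNode

from .otu import pairwise_identity

__all__ = [
    "AlignedBlock",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "align_representatives",
    "read_newick",
    "write_newick",
    "tree_splits",
]

#: Distance reported when the K2P logarithms saturate.
SATURATION_DISTANCE = 10.0

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class AlignedBlock:
    """An equal-length gapped alignment of named sequences."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset_columns(self, cols: Sequence[int]) -> "AlignedBlock":
        return AlignedBlock(
            ids=self.ids,
            rows=tuple("".join(r[c] for c in cols) for r in self.rows),
        )


def k2p_distance(row_a: str, row_b: str) -> float:
    """Kimura two-parameter distance between two aligned rows.

    Columns where either row carries a gap or ambiguity are excluded
    (pairwise deletion). With P the transition and Q the transversion
    proportion, d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q). Saturated
    pairs (either logarithm undefined) are reported as the flagged
    maximum ``SATURATION_DISTANCE``.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    a = np.frombuffer(row_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode("ascii"), dtype=np.uint8)
    # class codes: purine 1, pyrimidine 2, other 0
    cls = np.zeros(256, dtype=np.uint8)
    cls[[ord("A"), ord("G")]] = 1
    cls[[ord("C"), ord("T")]] = 2
    ca, cb = cls[a], cls[b]
    comparable = (ca > 0) & (cb > 0)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable columns between rows")
    diff = comparable & (a != b)
    transitions = int((diff & (ca == cb)).sum())
    transversions = int(diff.sum()) - transitions
    P, Q = transitions / n, transversions / n
    x, y = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if x <= 0.0 or y <= 0.0:
        return SATURATION_DISTANCE
    return -0.5 * math.log(x) - 0.25 * math.log(y)


def k2p_matrix(aln: AlignedBlock) -> tuple[tuple[str, ...], np.ndarray]:
    """All-pairs K2P distance matrix for an alignment."""
    n = len(aln.ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(aln.rows[i], aln.rows[j])
            dm[i, j] = dm[j, i] = d
    return aln.ids, dm


def nj_tree(dm: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Returns an unrooted tree represented with a trifurcating root.
    Negative branch lengths are clamped to zero with the deficit moved
    to the sister branch (standard convention).
    """
    dm = np.asarray(dm, dtype=float)
    n = len(ids)
    if dm.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (dm < 0).any():
        raise ValueError("distance matrix entries must be non-negative")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]
    D = dm.copy()
    active = list(range(n))

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        parent = TreeNode()
        ci, cj = nodes[ai], nodes[aj]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0])
        for k_idx, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            new_row[ak] = 0.5 * (D[ai, ak] + D[aj, ak] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        new_index = D.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_index]

    # join the last three nodes at a trifurcating root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = float(max(ln, 0.0))
        root.append(node)
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Unrooted bipartitions as canonical leaf-name sets.

    Each internal edge is encoded by the smaller side of its split
    (ties broken lexicographically) so that topologically identical
    unrooted trees yield identical split sets regardless of rooting.
    """
    leaves = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        splits.add(frozenset(canonical))
    return splits


def bootstrap_support(
    aln: AlignedBlock, n_replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with bipartition bootstrap supports in [0, 1].

    Columns are resampled with replacement per replicate (replicate r
    draws from an RNG seeded by (seed, r), so runs are reproducible and
    order-independent); each internal edge of the full-data tree is
    annotated with the fraction of replicate trees containing its
    bipartition. Alignments with fewer than 4 rows have no internal
    edges and are returned unannotated.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, dm = k2p_matrix(aln)
    tree = nj_tree(dm, ids)
    if len(aln.ids) < 4:
        return tree

    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    ncol = aln.n_cols
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = aln.subset_columns(cols.tolist())
        rep_ids, rep_dm = k2p_matrix(rep_aln)
        rep_splits = tree_splits(nj_tree(rep_dm, rep_ids))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    leaves = frozenset(aln.ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        # skbio writes the `support` attribute as the internal node label
        node.support = counts.get(canonical, 0) / n_replicates
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# --- progressive (center-star) alignment ------------------------------

def _pairwise_global(aligner: Align.PairwiseAligner, a: str, b: str):
    """Best global alignment of b against center a, as two gapped rows."""
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_representatives(seqs: Sequence[tuple[str, str]]) -> AlignedBlock:
    """Deterministic center-star multiple alignment with affine gaps.

    The center is the sequence with the highest summed pairwise identity
    to the rest (ties by id); every other sequence is globally aligned
    to the center and the pairwise alignments are merged column-wise
    ("once a gap, always a gap"). Identical inputs yield an ungapped
    block; the column count is never below the longest input.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 1:
        return AlignedBlock(ids=(ids[0],), rows=(seqs[0][1],))

    # pick the center by summed identity
    best_id, best_score = None, -1.0
    for i, (sid, s) in enumerate(seqs):
        total = sum(
            pairwise_identity(s, t) for j, (_, t) in enumerate(seqs) if j != i
        )
        if total > best_score or (total == best_score and sid < str(best_id)):
            best_id, best_score = sid, total
    center_seq = dict(seqs)[best_id]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5

    others = [(sid, s) for sid, s in seqs if sid != best_id]
    pair_rows = []
    for sid, s in others:
        c_row, s_row = _pairwise_global(aligner, center_seq, s)
        pair_rows.append((sid, c_row, s_row))

    # gaps[k] = max gaps inserted before center position k (k=0..L)
    L = len(center_seq)
    gaps = [0] * (L + 1)
    for _, c_row, _ in pair_rows:
        pos = run = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                gaps[pos] = max(gaps[pos], run)
                run = 0
                pos += 1
        gaps[L] = max(gaps[L], run)

    def project_center() -> str:
        out = []
        for k in range(L):
            out.append("-" * gaps[k])
            out.append(center_seq[k])
        out.append("-" * gaps[L])
        return "".join(out)

    def project(c_row: str, s_row: str) -> str:
        out = []
        pos, run = 0, []
        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == "-":
                run.append(s_ch)
            else:
                out.append("-" * (gaps[pos] - len(run)) + "".join(run))
                out.append(s_ch)
                run = []
                pos += 1
        out.append("-" * (gaps[L] - len(run)) + "".join(run))
        return "".join(out)

    rows = {best_id: project_center()}
    for sid, c_row, s_row in pair_rows:
        rows[sid] = project(c_row, s_row)
    return AlignedBlock(ids=tuple(ids), rows=tuple(rows[i] for i in ids))
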