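"""MEGAN-style lowest-common-ancestor taxonomic binning.

Per-read hit filtering (E-value, min bit score, top-percent of the best
score), naive LCA placement on a ranked lineage table, min-support
pruning, group summaries, and a built-in read-vs-reference aligner so
the whole stage runs without an external BLAST installation.

Default filter values are the study's settings: E <= 1e-5, min-score 5
bits, top-percent 1, min-support 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io import DataError, Hit, RawRead
from .simulate import ReferenceRecord

__all__ = [
    "TaxonomyTree",
    "AssignmentResult",
    "NO_HITS",
    "NOT_ASSIGNED",
    "filter_hits",
    "assign_lca",
    "assign_reads",
    "apply_min_support",
    "summarize_groups",
    "align_reads",
    "parse_lineage_table",
]

NO_HITS = "No hits"
NOT_ASSIGNED = "Not assigned"
ROOT = "root"


def parse_lineage_table(table: pd.DataFrame) -> dict[str, tuple[tuple[str, str], ...]]:
    """Decode a lineage table (ref_id, 'rank:name;rank:name;...')."""
    out: dict[str, tuple[tuple[str, str], ...]] = {}
    for ref_id, lineage in zip(table["ref_id"], table["lineage"]):
        path = []
        if isinstance(lineage, str) and lineage:
            for part in lineage.split(";"):
                rank, _, name = part.partition(":")
                path.append((rank, name))
        out[str(ref_id)] = tuple(path)
    return out


@dataclass
class _Node:
    node_id: str
    name: str
    rank: str
    parent: str | None
    count: int = 0  # reads assigned directly to this node


class TaxonomyTree:
    """Ranked lineage tree with per-node direct read tallies.

    Reserved bins "No hits" and "Not assigned" sit outside the tree
    proper but are included in totals, so that
    assigned + not-assigned + no-hits always equals the number of
    input reads.
    """

    def __init__(self, lineages: Mapping[str, tuple[tuple[str, str], ...]]):
        self._nodes: dict[str, _Node] = {
            ROOT: _Node(ROOT, ROOT, "root", None)
        }
        self.reserved: dict[str, int] = {NO_HITS: 0, NOT_ASSIGNED: 0}
        self._lineages = dict(lineages)
        for path in self._lineages.values():
            self._ensure_path(path)

    def _ensure_path(self, path: tuple[tuple[str, str], ...]) -> str:
        parent = ROOT
        for rank, name in path:
            nid = f"{parent}/{name}"
            if nid not in self._nodes:
                self._nodes[nid] = _Node(nid, name, rank, parent)
            parent = nid
        return parent

    def node_id_for_path(self, path: tuple[tuple[str, str], ...]) -> str:
        return self._ensure_path(path)

    @property
    def nodes(self) -> dict[str, _Node]:
        return self._nodes

    def parent(self, node_id: str) -> str | None:
        return self._nodes[node_id].parent

    def children(self, node_id: str) -> list[str]:
        return [n.node_id for n in self._nodes.values() if n.parent == node_id]

    def add_count(self, node_id: str, n: int = 1) -> None:
        if node_id in self.reserved:
            self.reserved[node_id] += n
        else:
            self._nodes[node_id].count += n

    def direct_count(self, node_id: str) -> int:
        if node_id in self.reserved:
            return self.reserved[node_id]
        return self._nodes[node_id].count

    def cumulative_count(self, node_id: str) -> int:
        """Reads assigned to the node or any descendant."""
        if node_id in self.reserved:
            return self.reserved[node_id]
        total = self._nodes[node_id].count
        for child in self.children(node_id):
            total += self.cumulative_count(child)
        return total

    def total_reads(self) -> int:
        return self.cumulative_count(ROOT) + sum(self.reserved.values())

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if `a` is an ancestor of (or equal to) `b`."""
        cur: str | None = b
        while cur is not None:
            if cur == a:
                return True
            cur = self._nodes[cur].parent
        return False

    def counts_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n.node_id,
                "name": n.name,
                "rank": n.rank,
                "direct": n.count,
                "cumulative": self.cumulative_count(n.node_id),
            }
            for n in self._nodes.values()
        ]
        for name, c in self.reserved.items():
            rows.append(
                {"node": name, "name": name, "rank": "reserved",
                 "direct": c, "cumulative": c}
            )
        return pd.DataFrame(rows)


def filter_hits(
    hits: Sequence[Hit],
    e_max: float = 1e-5,
    min_score: float = 5.0,
    top_percent: float = 1.0,
) -> list[Hit]:
    """Retain one read's hits passing the E-value, min-score and
    top-percent filters.

    A hit survives iff e_value <= e_max, bit_score >= min_score, and its
    bit score lies within `top_percent` percent of the best score among
    the hits that passed the first two filters. Ties at the boundary are
    retained. Idempotent.
    """
    if e_max <= 0 or min_score <= 0 or top_percent <= 0:
        raise ValueError("filter parameters must be positive")
    prefiltered = [
        h for h in hits if h.e_value <= e_max and h.bit_score >= min_score
    ]
    if not prefiltered:
        return []
    best = max(h.bit_score for h in prefiltered)
    floor = (1.0 - top_percent / 100.0) * best
    return [h for h in prefiltered if h.bit_score >= floor]


def assign_lca(
    retained: Sequence[Hit],
    lineages: Mapping[str, tuple[tuple[str, str], ...]],
) -> tuple[tuple[str, str], ...] | str:
    """Place a read at the lowest common ancestor of its retained hits.

    Returns the LCA lineage path, or the reserved bin names: "No hits"
    when nothing was retained, "Not assigned" when the retained hits map
    only to references without a resolvable lineage below the root.
    """
    if not retained:
        return NO_HITS
    paths = []
    for h in retained:
        if h.ref_id not in lineages:
            raise DataError(f"ref_id {h.ref_id!r} missing from lineage table")
        paths.append(lineages[h.ref_id])
    paths = [p for p in paths if p]
    if not paths:
        return NOT_ASSIGNED
    # longest common prefix of the lineage paths
    common: list[tuple[str, str]] = []
    for nodes in zip(*paths):
        if all(n == nodes[0] for n in nodes[1:]):
            common.append(nodes[0])
        else:
            break
    # hits spanning the whole tree legitimately place the read at the root
    return tuple(common)


@dataclass
class AssignmentResult:
    """Per-read LCA assignments plus a filter audit."""

    assignments: dict[str, str]  # read_id -> node id or reserved bin
    tree: TaxonomyTree
    hits_seen: int = 0
    hits_retained: int = 0


def assign_reads(
    hits: Sequence[Hit],
    lineages: Mapping[str, tuple[tuple[str, str], ...]],
    read_ids: Sequence[str] | None = None,
    e_max: float = 1e-5,
    min_score: float = 5.0,
    top_percent: float = 1.0,
    min_support: int = 1,
) -> AssignmentResult:
    """Filter + LCA + min-support for a whole read set.

    `read_ids`, when given, lists every read in the sample so that reads
    with no hits at all are tallied in the "No hits" bin.
    """
    by_read: dict[str, list[Hit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    all_reads = list(read_ids) if read_ids is not None else list(by_read)

    tree = TaxonomyTree(lineages)
    assignments: dict[str, str] = {}
    seen = retained_n = 0
    for rid in all_reads:
        rhits = by_read.get(rid, [])
        seen += len(rhits)
        kept = filter_hits(rhits, e_max=e_max, min_score=min_score,
                           top_percent=top_percent)
        retained_n += len(kept)
        placed = assign_lca(kept, lineages)
        if isinstance(placed, str):
            node = placed
        else:
            node = tree.node_id_for_path(placed)
        assignments[rid] = node
        tree.add_count(node)
    if min_support > 1:
        apply_min_support(tree, min_support)
    return AssignmentResult(
        assignments=assignments, tree=tree,
        hits_seen=seen, hits_retained=retained_n,
    )


def apply_min_support(tree: TaxonomyTree, min_support: int = 1) -> TaxonomyTree:
    """Push reads on weakly supported nodes up to their ancestors.

    Nodes whose direct count is positive but below `min_support` have
    those reads re-assigned to the parent, processed deepest-first so
    the reads keep climbing until they rest on a node whose cumulative
    count reaches the threshold (or the root). With min_support=1 (the
    study's setting) the tree is unchanged. Total reads are conserved.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support == 1:
        return tree

    def depth(nid: str) -> int:
        d = 0
        cur = tree.parent(nid)
        while cur is not None:
            d += 1
            cur = tree.parent(cur)
        return d

    for nid in sorted(tree.nodes, key=depth, reverse=True):
        if nid == ROOT:
            continue
        node = tree.nodes[nid]
        if 0 < node.count and tree.cumulative_count(nid) < min_support:
            parent = node.parent or ROOT
            tree.nodes[parent].count += node.count
            node.count = 0
    return tree


def summarize_groups(
    tree: TaxonomyTree, grouping_nodes: Sequence[str]
) -> pd.DataFrame:
    """Read counts and percentages for chosen taxonomic groups.

    Percentages are relative to the total reads in the sample (including
    the reserved bins); a remainder row tops the table up to 100%.
    Grouping nodes must be non-overlapping (no ancestor/descendant pairs).
    """
    for g in grouping_nodes:
        if g not in tree.nodes:
            raise ValueError(f"grouping node {g!r} not in tree")
    for a in grouping_nodes:
        for b in grouping_nodes:
            if a != b and tree.is_ancestor(a, b):
                raise ValueError(f"overlapping grouping nodes: {a!r} contains {b!r}")
    total = tree.total_reads()
    if total == 0:
        raise ValueError("empty sample: group percentages undefined")
    rows = []
    covered = 0
    for g in grouping_nodes:
        c = tree.cumulative_count(g)
        covered += c
        rows.append({"group": g, "reads": c, "percent": 100.0 * c / total})
    rest = total - covered
    rows.append({"group": "remainder", "reads": rest,
                 "percent": 100.0 * rest / total})
    return pd.DataFrame(rows)


# --- built-in aligner -------------------------------------------------

# BLASTN-like scoring and Karlin-Altschul parameters for
# match +2 / mismatch -3 / gap open 5 / gap extend 2.
_LAMBDA = 0.625
_K = 0.41


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_reads(
    reads: Sequence[RawRead],
    db: Sequence[ReferenceRecord],
    k: int = 11,
    max_targets: int = 8,
    top_k: int = 10,
    e_max: float = 10.0,
    exhaustive: bool = False,
) -> list[Hit]:
    """Local-align reads against the reference set, BLAST-tabular style.

    Candidate references are pre-screened by shared exact k-mers
    (default k=11); candidates are then aligned with an exact local
    (Smith-Waterman) alignment and scored with a bit score and
    Karlin-Altschul-style E-value. With ``exhaustive=True`` the k-mer
    screen is skipped and every reference is aligned (the slow oracle
    path).
    """
    if not reads or not db:
        raise ValueError("reads and references must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2

    ref_kmers = {r.ref_id: _kmers(r.sequence, k) for r in db}
    ref_seq = {r.ref_id: r.sequence for r in db}
    db_len = sum(len(r.sequence) for r in db)

    hits: list[Hit] = []
    for read in reads:
        if exhaustive:
            candidates = [r.ref_id for r in db]
        else:
            rk = _kmers(read.sequence, k)
            scored = [
                (len(rk & ref_kmers[r.ref_id]), r.ref_id) for r in db
            ]
            scored = [(c, rid) for c, rid in scored if c > 0]
            scored.sort(key=lambda t: (-t[0], t[1]))
            candidates = [rid for _, rid in scored[:max_targets]]
        read_hits = []
        for rid in candidates:
            aln = aligner.align(read.sequence, ref_seq[rid])[0]
            counts = aln.counts()
            identities, mismatches = counts.identities, counts.mismatches
            gaps = counts.gaps
            aln_len = identities + mismatches + gaps
            if aln_len == 0:
                continue
            score = aln.score
            bit = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
            evalue = len(read.sequence) * db_len * 2.0 ** (-bit)
            if evalue > e_max:
                continue
            qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
            gap_open = (
                counts.open_internal_insertions + counts.open_internal_deletions
            )
            read_hits.append(
                Hit(
                    read_id=read.read_id,
                    ref_id=rid,
                    percent_identity=round(100.0 * identities / aln_len, 2),
                    align_length=aln_len,
                    mismatch=mismatches,
                    gap_open=gap_open,
                    qstart=qs + 1,
                    qend=qe,
                    sstart=ss + 1,
                    send=se,
                    e_value=evalue,
                    bit_score=round(bit, 1),
                )
            )
        read_hits.sort(key=lambda h: (-h.bit_score, h.ref_id))
        hits.extend(read_hits[:top_k])
    return hits
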