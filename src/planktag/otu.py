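"""Greedy centroid OTU clustering and diversity statistics.

Implements the study's sequence-diversity workflow: 97%-identity greedy
clustering, taxon validation at a minimum cluster size (3 reads),
longest->400-nt representative selection, Chao1 / Shannon / Margalef /
Simpson indices, analytic and Monte-Carlo rarefaction, and the
normalized relative-change statistic comparing two sampling dates.

The Chao1 estimator follows the study's own definition of its inputs:
``n1`` is the number of singleton OTUs and ``n2`` the number of OTUs
with two reads *or more* (not exact doubletons); the classical
doubleton variant is available via ``classic_n2=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import edlib
import numpy as np
from scipy.special import gammaln

from .io import RawRead

__all__ = [
    "OTU",
    "AbundanceVector",
    "DiversitySummary",
    "RelativeChange",
    "pairwise_identity",
    "cluster_greedy",
    "validate_taxa",
    "chao1",
    "chao1_detail",
    "shannon",
    "margalef",
    "simpson",
    "diversity_summary",
    "rarefaction_curve",
    "relative_change",
    "abundance_vectors_from_otus",
]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Semi-global percent identity between two sequences, in [0, 1].

    The shorter sequence is aligned inside the longer one with free end
    gaps on the longer sequence (infix/"glocal" alignment), so truncated
    reads score high identity against their full-length centroid.
    Identity is 1 - d/L with d the minimal semi-global edit distance and
    L the shorter sequence's length; this is unique (unlike
    matches-over-columns, which depends on the co-optimal path chosen)
    and symmetric by construction.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) <= len(seq_b):
        query, target = seq_a, seq_b
    else:
        query, target = seq_b, seq_a
    d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(query))


@dataclass
class OTU:
    """One cluster: centroid, members, per-sample counts, representative.

    The representative is the longest member read exceeding the
    representative length floor (400 nt by default), ties broken by read
    id; clusters with no member above the floor have none.
    """

    otu_id: str
    centroid_id: str
    members: list[str]
    per_sample: dict[str, int] = field(default_factory=dict)
    representative_id: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_greedy(
    reads: Sequence[RawRead],
    identity_threshold: float = 0.97,
    sample_of: Mapping[str, str] | None = None,
    representative_min_len: int = 400,
) -> list[OTU]:
    """Greedy centroid clustering at an identity threshold.

    Reads are processed in decreasing length order (ties by read id);
    the first read seeds the first centroid and each subsequent read
    joins the first existing centroid whose pairwise identity reaches
    the threshold, else founds a new one. Deterministic by construction.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0.5, 1]")
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))
    seqs = {r.read_id: r.sequence for r in ordered}

    centroids: list[tuple[str, str]] = []  # (read_id, sequence)
    membership: dict[str, list[str]] = {}
    for read in ordered:
        placed = False
        for cid, cseq in centroids:
            if pairwise_identity(read.sequence, cseq) >= identity_threshold:
                membership[cid].append(read.read_id)
                placed = True
                break
        if not placed:
            centroids.append((read.read_id, read.sequence))
            membership[read.read_id] = [read.read_id]

    otus = []
    for i, (cid, _) in enumerate(centroids, start=1):
        members = membership[cid]
        longest = max(members, key=lambda m: (len(seqs[m]), m))
        rep = longest if len(seqs[longest]) > representative_min_len else None
        per_sample: dict[str, int] = {}
        if sample_of is not None:
            for m in members:
                s = sample_of.get(m, "unknown")
                per_sample[s] = per_sample.get(s, 0) + 1
        otus.append(
            OTU(
                otu_id=f"OTU_{i:04d}",
                centroid_id=cid,
                members=members,
                per_sample=per_sample,
                representative_id=rep,
            )
        )
    return otus


def validate_taxa(
    otus: Sequence[OTU], min_reads: int = 3
) -> tuple[list[OTU], list[OTU]]:
    """Split OTUs into (validated, rejected) by minimum member count.

    A taxon is validated when its cluster holds at least `min_reads`
    reads (3 in the study). The two lists partition the input.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    validated = [o for o in otus if o.size >= min_reads]
    rejected = [o for o in otus if o.size < min_reads]
    return validated, rejected


@dataclass(frozen=True)
class AbundanceVector:
    """Per-OTU read counts for one sample."""

    sample_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    @property
    def S(self) -> int:
        return sum(1 for c in self.counts if c > 0)

    @property
    def p(self) -> np.ndarray:
        if self.N == 0:
            raise ValueError("empty abundance vector")
        arr = np.array([c for c in self.counts if c > 0], dtype=float)
        return arr / arr.sum()


def abundance_vectors_from_otus(
    otus: Sequence[OTU], sample_ids: Sequence[str]
) -> dict[str, AbundanceVector]:
    """Per-sample abundance vectors from clustered OTUs."""
    return {
        s: AbundanceVector(
            sample_id=s,
            counts=tuple(o.per_sample.get(s, 0) for o in otus),
        )
        for s in sample_ids
    }


class _Chao1Detail(NamedTuple):
    value: float
    S: int
    n1: int
    n2: int
    degenerate: bool


def chao1_detail(av: AbundanceVector, classic_n2: bool = False) -> _Chao1Detail:
    """Chao1 richness with its ingredients and degenerate-case flag.

    Uses the study's definition n2 = number of OTUs with >= 2 reads;
    ``classic_n2=True`` switches to exact doubletons. When n2 = 0 the
    bias-corrected fallback S + n1(n1-1)/2 is used and flagged.
    """
    if av.N == 0:
        raise ValueError("empty abundance vector")
    S = av.S
    n1 = sum(1 for c in av.counts if c == 1)
    if classic_n2:
        n2 = sum(1 for c in av.counts if c == 2)
    else:
        n2 = sum(1 for c in av.counts if c >= 2)
    if n2 == 0:
        return _Chao1Detail(S + n1 * (n1 - 1) / 2.0, S, n1, n2, True)
    return _Chao1Detail(S + n1 * n1 / (2.0 * n2), S, n1, n2, False)


def chao1(av: AbundanceVector, classic_n2: bool = False) -> float:
    return chao1_detail(av, classic_n2=classic_n2).value


def shannon(av: AbundanceVector, base: float | None = None) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (natural log by default)."""
    p = av.p
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(0.0, h)


def margalef(av: AbundanceVector) -> float:
    """Margalef richness d = (S - 1) / ln N; defined as 0 when N = 1."""
    if av.N == 0:
        raise ValueError("empty abundance vector")
    if av.N == 1:
        return 0.0
    return (av.S - 1) / math.log(av.N)


def simpson(av: AbundanceVector, variant: str = "gini") -> float:
    """Simpson's index.

    variant="gini": 1 - sum p_i^2 (complement, default);
    variant="dominance": sum p_i^2;
    variant="unbiased": 1 - sum n_i(n_i-1) / (N(N-1)).
    """
    p = av.p
    d = float((p * p).sum())
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "unbiased":
        N = av.N
        if N < 2:
            raise ValueError("unbiased Simpson needs N >= 2")
        num = sum(c * (c - 1) for c in av.counts)
        return 1.0 - num / (N * (N - 1))
    raise ValueError(f"unknown Simpson variant {variant!r}")


@dataclass(frozen=True)
class DiversitySummary:
    """One sample's row of the diversity report."""

    sample_id: str
    N: int
    S: int
    n1: int
    n2: int
    chao1: float
    chao1_degenerate: bool
    shannon: float
    margalef: float
    simpson: float


def diversity_summary(av: AbundanceVector) -> DiversitySummary:
    det = chao1_detail(av)
    return DiversitySummary(
        sample_id=av.sample_id,
        N=av.N,
        S=det.S,
        n1=det.n1,
        n2=det.n2,
        chao1=det.value,
        chao1_degenerate=det.degenerate,
        shannon=shannon(av),
        margalef=margalef(av),
        simpson=simpson(av),
    )


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(
    av: AbundanceVector,
    depths: Sequence[int],
    mode: str = "analytic",
    n_reps: int = 1000,
    seed: int | None = None,
) -> list[tuple[int, float]]:
    """Expected OTU count in a random subsample at each depth.

    Analytic mode evaluates the hypergeometric expectation
    E[S_n] = sum_i (1 - C(N - n_i, n) / C(N, n)); Monte-Carlo mode
    subsamples reads without replacement `n_reps` times.
    """
    N = av.N
    if N == 0:
        raise ValueError("empty abundance vector")
    if any(d < 0 or d > N for d in depths):
        raise ValueError("depths must lie in [0, N]")
    counts = np.array([c for c in av.counts if c > 0], dtype=int)

    if mode == "analytic":
        out = []
        for n in depths:
            log_denom = _log_comb(N, n)
            total = 0.0
            for ni in counts:
                if N - ni < n:
                    total += 1.0
                else:
                    total += 1.0 - math.exp(_log_comb(N - ni, n) - log_denom)
            out.append((int(n), total))
        return out

    if mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(counts)), counts)
        out = []
        for n in depths:
            seen = [
                len(np.unique(rng.choice(labels, size=n, replace=False)))
                for _ in range(n_reps)
            ]
            out.append((int(n), float(np.mean(seen))))
        return out

    raise ValueError(f"unknown rarefaction mode {mode!r}")


@dataclass(frozen=True)
class RelativeChange:
    """Normalized fold change of one taxon between two sampling dates.

    R = (n_iB / N_B) / (n_iA / N_A). A taxon absent on the first date is
    flagged "new" (R undefined); absent on the second date, "lost"
    (R = 0).
    """

    n_iA: int
    n_iB: int
    N_A: int
    N_B: int
    R: float
    status: str  # "ok" | "new" | "lost" | "absent"


def relative_change(n_iA: int, n_iB: int, N_A: int, N_B: int) -> RelativeChange:
    if min(n_iA, n_iB) < 0:
        raise ValueError("read counts must be non-negative")
    if N_A <= 0 or N_B <= 0:
        raise ValueError("sample totals must be positive")
    if n_iA == 0 and n_iB == 0:
        return RelativeChange(n_iA, n_iB, N_A, N_B, math.nan, "absent")
    if n_iA == 0:
        return RelativeChange(n_iA, n_iB, N_A, N_B, math.inf, "new")
    if n_iB == 0:
        return RelativeChange(n_iA, n_iB, N_A, N_B, 0.0, "lost")
    R = (n_iB / N_B) / (n_iA / N_A)
    return RelativeChange(n_iA, n_iB, N_A, N_B, R, "ok")
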