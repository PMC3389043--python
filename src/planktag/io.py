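"""File formats and read pre-processing.

FASTA in/out (Biopython), tag+key demultiplexing with primer stripping,
read-length QC, and BLAST tabular (outfmt 6) hit tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import TagScheme

__all__ = [
    "RawRead",
    "SampleReadSet",
    "Hit",
    "DataError",
    "read_fasta",
    "write_fasta",
    "demultiplex",
    "length_stats",
    "read_hit_table",
    "write_hit_table",
]

_ALPHABET = set("ACGTN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class RawRead(NamedTuple):
    read_id: str
    sequence: str


@dataclass
class SampleReadSet:
    """Cleaned reads (tag, key and primer removed) for one sample."""

    sample_id: str
    reads: list[RawRead] = field(default_factory=list)
    date_label: str = ""

    def __len__(self) -> int:
        return len(self.reads)


def read_fasta(path: str | Path) -> list[RawRead]:
    path = Path(path)
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"{path}: record {i} ({rec.id}) has empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise DataError(
                f"{path}: record {i} ({rec.id}) has invalid characters {sorted(bad)}"
            )
        out.append(RawRead(rec.id, seq))
    return out


def write_fasta(reads: Iterable[RawRead | tuple[str, str]], path: str | Path) -> None:
    recs = (
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads
    )
    SeqIO.write(recs, str(path), "fasta")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def demultiplex(
    reads: Sequence[RawRead],
    scheme: TagScheme,
    primer_mismatches: int = 1,
    trim_reverse_primer: bool = True,
) -> tuple[dict[str, SampleReadSet], list[RawRead]]:
    """Partition raw reads by 10-nt tag + TCAG key, stripping the primer.

    A read is assigned iff its first 10 nt exactly match a sample tag,
    the next 4 nt equal the key, and the forward primer follows within
    the given mismatch budget. Assigned reads are emitted with
    tag+key+primer removed (and the reverse-primer complement trimmed
    from the 3' end when present); everything else goes to the
    unassigned bin. Assignment is a partition of the input.
    """
    if primer_mismatches < 0:
        raise ValueError("primer_mismatches must be >= 0")
    tag_to_sample = {t: s for s, t in scheme.tags}
    if len(tag_to_sample) != len(scheme.tags):
        raise ValueError("duplicate tags in scheme")

    n_tag, n_key, n_fwd = 10, len(scheme.key), len(scheme.fwd_primer)
    rev_rc = _revcomp(scheme.rev_primer)
    by_sample = {s: SampleReadSet(sample_id=s) for s, _ in scheme.tags}
    unassigned: list[RawRead] = []
    for read in reads:
        seq = read.sequence
        tag = seq[:n_tag]
        sample = tag_to_sample.get(tag)
        if (
            sample is None
            or seq[n_tag : n_tag + n_key] != scheme.key
            or len(seq) < n_tag + n_key + n_fwd
            or _hamming(seq[n_tag + n_key : n_tag + n_key + n_fwd], scheme.fwd_primer)
            > primer_mismatches
        ):
            unassigned.append(read)
            continue
        insert = seq[n_tag + n_key + n_fwd :]
        if trim_reverse_primer and rev_rc:
            pos = insert.rfind(rev_rc)
            if pos >= 0:
                insert = insert[:pos]
        if not insert:
            unassigned.append(read)
            continue
        by_sample[sample].reads.append(RawRead(read.read_id, insert))
    return by_sample, unassigned


def length_stats(
    reads: SampleReadSet | Sequence[RawRead],
    thresholds: Sequence[int] = (200, 400),
) -> pd.DataFrame:
    """Fraction of reads whose length exceeds each threshold.

    For an empty read set the fractions are undefined and reported as
    NaN, never as 0.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    seqs = reads.reads if isinstance(reads, SampleReadSet) else list(reads)
    lengths = [len(r.sequence) for r in seqs]
    rows = []
    for t in sorted(thresholds):
        if not lengths:
            frac = math.nan
        else:
            frac = sum(ln > t for ln in lengths) / len(lengths)
        rows.append({"threshold": t, "fraction_above": frac})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Hit:
    """One alignment hit in BLAST outfmt-6 terms."""

    read_id: str
    ref_id: str
    percent_identity: float
    align_length: int
    mismatch: int
    gap_open: int
    qstart: int
    qend: int
    sstart: int
    send: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")


def read_hit_table(path: str | Path) -> list[Hit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file."""
    path = Path(path)
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise DataError(
                    f"{path}: row {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    Hit(
                        read_id=parts[0],
                        ref_id=parts[1],
                        percent_identity=float(parts[2]),
                        align_length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gap_open=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise DataError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.read_id,
                        h.ref_id,
                        f"{h.percent_identity:.2f}",
                        str(h.align_length),
                        str(h.mismatch),
                        str(h.gap_open),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.e_value:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
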