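"""Synthetic data generation for the tag-pyrosequencing pipeline.

Everything downstream of the sequencer is testable without real data:
this module fabricates a small ranked reference database (a stand-in for
an SSU rRNA reference), bloom-structured community profiles, tagged
454-style amplicon reads with point errors and length attrition, and
microscopy count tables with jittered cell dimensions.

All generators are driven by an explicit integer seed and are
bit-reproducible: the same seed yields byte-identical output. Truth
tables (read id -> source reference) are produced alongside reads so
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceRecord",
    "CommunityProfile",
    "TagScheme",
    "LengthModel",
    "MicroscopySpec",
    "FWD_PRIMER",
    "REV_PRIMER",
    "generate_reference_db",
    "generate_community",
    "generate_reads",
    "generate_microscopy_table",
    "lineage_table",
    "default_tag_scheme",
]

#: Universal eukaryote forward primer 18S-82F (amplifies the V2-V3 region).
FWD_PRIMER = "GAAACTGCGAATGGCTC"
#: Universal eukaryote reverse primer Ek-516r.
REV_PRIMER = "ACCAGACTTGCCCTCC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RANKS = ("family", "genus", "species")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with its ranked lineage.

    The lineage is an ordered (rank, name) path, coarsest rank first.
    """

    ref_id: str
    lineage: tuple[tuple[str, str], ...]
    sequence: str

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError("lineage must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence alphabet must be A/C/G/T")


@dataclass(frozen=True)
class CommunityProfile:
    """True relative abundances of the taxa in one sample."""

    sample_id: str
    taxa: tuple[tuple[str, float], ...]
    bloom_taxon: str | None = None

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total!r})")
        if any(a <= 0 for _, a in self.taxa):
            raise ValueError("abundances must be positive")
        if self.bloom_taxon is not None and self.bloom_taxon not in {
            r for r, _ in self.taxa
        }:
            raise ValueError("bloom_taxon must be a member of taxa")

    @property
    def abundances(self) -> dict[str, float]:
        return dict(self.taxa)


@dataclass(frozen=True)
class TagScheme:
    """Per-sample 10-nt tags plus the fixed 4-nt instrument key and primers."""

    tags: tuple[tuple[str, str], ...]  # (sample_id, tag)
    key: str = "TCAG"
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER

    def __post_init__(self) -> None:
        seqs = [t for _, t in self.tags]
        if len(set(seqs)) != len(seqs):
            raise ValueError("sample tags must be pairwise distinct")
        if any(len(t) != 10 for t in seqs):
            raise ValueError("tags must be 10 nt")
        if len(self.key) != 4:
            raise ValueError("key must be 4 nt")

    @property
    def tag_of(self) -> dict[str, str]:
        return dict(self.tags)


@dataclass(frozen=True)
class LengthModel:
    """Two-component 454-style length-attrition model.

    A read keeps its full insert with probability ``full_fraction``;
    otherwise it is truncated to a uniform length on
    ``[min_length, max_truncated)``. The defaults reproduce roughly 75%
    of reads above 200 bp and 40% above 400 bp for ~470-bp inserts.
    """

    full_fraction: float = 0.40
    min_length: int = 50
    max_truncated: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.full_fraction <= 1.0:
            raise ValueError("full_fraction must be in [0, 1]")
        if not 0 < self.min_length < self.max_truncated:
            raise ValueError("need 0 < min_length < max_truncated")


def default_tag_scheme(sample_ids: Sequence[str], seed: int = 0) -> TagScheme:
    """Draw distinct random 10-nt tags for the given samples."""
    rng = np.random.default_rng([seed, 2746])
    seen: set[str] = set()
    tags = []
    for sid in sample_ids:
        while True:
            t = "".join(chr(b) for b in rng.choice(_BASES, size=10))
            if t not in seen:
                seen.add(t)
                tags.append((sid, t))
                break
    return TagScheme(tags=tuple(tags))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Point-substitute each position independently with probability `rate`."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_reference_db(
    n_families: int,
    genera_per_family: int,
    species_per_genus: int,
    seed: int,
    seq_length: int = 500,
    genus_divergence: float = 0.02,
    family_divergence: float = 0.08,
    between_family_divergence: float = 0.15,
) -> list[ReferenceRecord]:
    """Generate a ranked reference database by mutating down a rank tree.

    A single ancestral sequence is mutated into family ancestors, those
    into genus ancestors, and those into species sequences, at per-branch
    substitution rates of half the stated pairwise divergence for each
    level. With the defaults, mean pairwise identity is highest within a
    genus (~98%), lower within a family (~92%) and lowest between
    families (~85%) -- enough separation for 97% OTU clustering and
    LCA assignment to be meaningful.
    """
    for name, v in (
        ("n_families", n_families),
        ("genera_per_family", genera_per_family),
        ("species_per_genus", species_per_genus),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1 (got {v})")

    rng = np.random.default_rng([seed, 101])
    root = _random_seq(rng, seq_length)
    records: list[ReferenceRecord] = []
    for f in range(1, n_families + 1):
        fam_name = f"Fam{f:02d}"
        fam_seq = _mutate(rng, root, between_family_divergence / 2.0)
        for g in range(1, genera_per_family + 1):
            gen_name = f"{fam_name}_Gen{g:02d}"
            gen_seq = _mutate(rng, fam_seq, family_divergence / 2.0)
            for s in range(1, species_per_genus + 1):
                sp_name = f"{gen_name}_sp{s:02d}"
                sp_seq = _mutate(rng, gen_seq, genus_divergence / 2.0)
                records.append(
                    ReferenceRecord(
                        ref_id=f"REF_F{f:02d}G{g:02d}S{s:02d}",
                        lineage=(
                            ("family", fam_name),
                            ("genus", gen_name),
                            ("species", sp_name),
                        ),
                        sequence=sp_seq.tobytes().decode("ascii"),
                    )
                )
    return records


def lineage_table(db: Sequence[ReferenceRecord]) -> pd.DataFrame:
    """Tabulate lineages as ``ref_id`` -> ``rank:name;rank:name;...``."""
    rows = [
        (r.ref_id, ";".join(f"{rank}:{name}" for rank, name in r.lineage))
        for r in db
    ]
    return pd.DataFrame(rows, columns=["ref_id", "lineage"])


def generate_community(
    db: Sequence[ReferenceRecord],
    n_taxa: int,
    bloom_fraction: float | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    decay: float = 0.6,
) -> CommunityProfile:
    """Draw a bloom-structured community over `n_taxa` reference taxa.

    Non-bloom taxa follow a geometric abundance series (ratio ``decay``);
    when ``bloom_fraction`` is given, the first drawn taxon is the bloom
    taxon and takes exactly that fraction, with the geometric series
    renormalised to the remainder.
    """
    if n_taxa > len(db):
        raise ValueError(f"n_taxa={n_taxa} exceeds database size {len(db)}")
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if bloom_fraction is not None and not 0.0 < bloom_fraction < 1.0:
        raise ValueError("bloom_fraction must be in (0, 1)")

    rng = np.random.default_rng([seed, 202])
    chosen = list(rng.choice(len(db), size=n_taxa, replace=False))
    ids = [db[i].ref_id for i in chosen]

    if bloom_fraction is None:
        w = decay ** np.arange(n_taxa)
        abund = w / w.sum()
        return CommunityProfile(
            sample_id=sample_id, taxa=tuple(zip(ids, abund.tolist()))
        )

    bloom_id = ids[0]
    rest = ids[1:]
    taxa: list[tuple[str, float]] = [(bloom_id, bloom_fraction)]
    if rest:
        w = decay ** np.arange(len(rest))
        w = w / w.sum() * (1.0 - bloom_fraction)
        taxa.extend(zip(rest, w.tolist()))
    else:
        taxa = [(bloom_id, 1.0)]
    return CommunityProfile(
        sample_id=sample_id, taxa=tuple(taxa), bloom_taxon=bloom_id
    )


def generate_reads(
    community: CommunityProfile,
    db: Sequence[ReferenceRecord],
    scheme: TagScheme,
    n_reads: int,
    error_rate: float = 0.005,
    length_model: LengthModel | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample tagged, error-laden amplicon reads from a community.

    Each raw read is ``tag + key + forward primer + insert`` where the
    insert is the (possibly truncated, point-mutated) reference sequence.
    Taxa are drawn multinomially from the community abundances.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)``
    pairs and truth is a DataFrame with columns read_id, ref_id.
    """
    if not community.taxa:
        raise ValueError("community is empty")
    if not 0.0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    lm = length_model or LengthModel()
    seqs = {r.ref_id: r.sequence for r in db}
    missing = [rid for rid, _ in community.taxa if rid not in seqs]
    if missing:
        raise ValueError(f"community taxa absent from db: {missing}")
    tag = scheme.tag_of.get(community.sample_id)
    if tag is None:
        raise ValueError(f"no tag for sample {community.sample_id!r}")

    rng = np.random.default_rng([seed, 303])
    ids = [rid for rid, _ in community.taxa]
    probs = np.array([a for _, a in community.taxa])
    counts = rng.multinomial(n_reads, probs)
    origins = np.repeat(np.arange(len(ids)), counts)
    rng.shuffle(origins)

    prefix = tag + scheme.key + scheme.fwd_primer
    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str]] = []
    for i, oi in enumerate(origins):
        rid = ids[oi]
        insert = np.frombuffer(seqs[rid].encode("ascii"), dtype=np.uint8)
        if rng.random() >= lm.full_fraction:
            cut = int(rng.integers(lm.min_length, lm.max_truncated))
            insert = insert[: min(cut, len(insert))]
        if error_rate > 0:
            insert = _mutate(rng, insert, error_rate)
        else:
            insert = insert.copy()
        read_id = f"{community.sample_id}_{i:06d}"
        reads.append((read_id, prefix + insert.tobytes().decode("ascii")))
        truth_rows.append((read_id, rid))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "ref_id"])
    return reads, truth


@dataclass(frozen=True)
class MicroscopySpec:
    """One taxon's microscopy parameters for table generation.

    ``abundance`` maps date label -> cells per litre. ``dimensions`` are
    (mean, sd) pairs in µm, in the order the shape expects.
    """

    taxon: str
    group: str
    shape: str
    abundance: Mapping[str, float]
    dimensions: tuple[tuple[float, float], ...]
    trophic: str = "auto"


def generate_microscopy_table(
    groups: Sequence[MicroscopySpec], seed: int = 0
) -> pd.DataFrame:
    """Emit a plankton count table with lognormally jittered dimensions.

    One row per taxon per date. Dimension jitter uses a lognormal with
    coefficient of variation sd/mean, mean-preserving; sd=0 reproduces
    the mean exactly.
    """
    from . import biomass as _biomass  # local import to avoid cycle

    rng = np.random.default_rng([seed, 404])
    rows = []
    for spec in groups:
        if spec.shape not in _biomass.SHAPES:
            raise ValueError(
                f"unknown shape {spec.shape!r}; known: {sorted(_biomass.SHAPES)}"
            )
        if _biomass.SHAPES[spec.shape].n_dims != len(spec.dimensions):
            raise ValueError(
                f"shape {spec.shape!r} expects "
                f"{_biomass.SHAPES[spec.shape].n_dims} dimensions"
            )
        for date in spec.abundance:
            ab = spec.abundance[date]
            if ab < 0:
                raise ValueError("abundances must be >= 0")
            dims = []
            for mean, sd in spec.dimensions:
                if sd == 0:
                    dims.append(mean)
                else:
                    cv = sd / mean
                    sigma = np.sqrt(np.log1p(cv * cv))
                    dims.append(
                        float(
                            mean
                            * np.exp(rng.normal(0.0, sigma) - sigma * sigma / 2)
                        )
                    )
            row = {
                "taxon": spec.taxon,
                "group": spec.group,
                "trophic": spec.trophic,
                "shape": spec.shape,
                "date": date,
                "abundance_cells_per_l": ab,
            }
            for k, d in enumerate(dims, start=1):
                row[f"dim{k}_um"] = d
            rows.append(row)
    df = pd.DataFrame(rows)
    if "dim2_um" not in df.columns and not df.empty:
        df["dim2_um"] = np.nan
    return df
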