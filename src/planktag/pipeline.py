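"""End-to-end pipeline orchestration and report tables.

Runs simulate -> demultiplex -> align/assign -> cluster -> diversity ->
phylogeny -> biomass with one configuration object whose defaults are
the study's analysis settings (E 1e-5, min-score 5, top-percent 1,
min-support 1, 97% identity, 3-read taxon validation, 400-nt
representative floor, 1000 bootstrap replicates). All randomness flows
from the single config seed through named per-stage substreams, so a
run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomass as bm
from . import io as pio
from . import lca, otu, phylo, simulate

__all__ = [
    "PipelineConfig",
    "ReadLedger",
    "RunReport",
    "run_pipeline",
    "compare_samples",
    "stage_seed",
]


def stage_seed(seed: int, stage: str) -> list[int]:
    """Derive a named substream seed from the master seed."""
    return [int(seed), zlib.crc32(stage.encode()) % (2**31)]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's values."""

    seed: int = 0
    # simulation
    n_families: int = 4
    genera_per_family: int = 2
    species_per_genus: int = 2
    n_taxa: int = 10
    bloom_fraction: float = 0.9
    n_reads_a: int = 300
    n_reads_b: int = 300
    error_rate: float = 0.005
    community_decay: float = 0.85
    # length-attrition model (454-style); full_length_fraction=1 disables
    # truncation entirely
    full_length_fraction: float = 0.40
    truncation_min: int = 50
    truncation_max: int = 400
    sample_a: str = "March31"
    sample_b: str = "April21"
    # hit filtering / LCA
    evalue: float = 1e-5
    min_score: float = 5.0
    top_percent: float = 1.0
    min_support: int = 1
    # clustering / validation
    identity: float = 0.97
    min_reads: int = 3
    representative_min_len: int = 400
    # phylogeny
    bootstrap_replicates: int = 1000
    # demux
    primer_mismatches: int = 1

    def validate(self) -> None:
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")
        if not 0 < self.bloom_fraction < 1:
            raise ValueError("bloom_fraction must be in (0, 1)")
        if self.evalue <= 0 or self.min_score <= 0 or self.top_percent <= 0:
            raise ValueError("filter parameters must be positive")
        if self.min_support < 1 or self.min_reads < 1:
            raise ValueError("min_support and min_reads must be >= 1")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


class ReadLedger:
    """Per-stage read accounting: inputs = outputs + itemized drops."""

    def __init__(self) -> None:
        self._rows: list[dict] = []

    def record(self, stage: str, sample: str, n_in: int, n_out: int,
               drops: dict[str, int] | None = None) -> None:
        drops = drops or {}
        dropped = sum(drops.values())
        if n_in != n_out + dropped:
            raise ValueError(
                f"ledger violation at {stage}/{sample}: "
                f"{n_in} != {n_out} + {dropped}"
            )
        self._rows.append(
            {"stage": stage, "sample": sample, "in": n_in, "out": n_out,
             "dropped": dropped, "drop_detail": dict(drops)}
        )

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def sample_totals(self, stage: str) -> dict[str, int]:
        return {
            r["sample"]: r["in"] for r in self._rows if r["stage"] == stage
        }

    def total_reads(self, stage: str) -> int:
        return sum(self.sample_totals(stage).values())


@dataclass
class RunReport:
    """All tables a pipeline run produces."""

    config: PipelineConfig
    ledger: ReadLedger
    qc: pd.DataFrame
    diversity: pd.DataFrame
    group_proportions: dict[str, pd.DataFrame]
    otu_table: pd.DataFrame
    relative_changes: pd.DataFrame
    biomass_stocks: pd.DataFrame
    fold_changes: pd.DataFrame
    newick: str | None
    bloom_taxon: str | None
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ledger.table.drop(columns=["drop_detail"]).to_csv(
            outdir / "read_ledger.tsv", sep="\t", index=False
        )
        self.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        self.diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        self.otu_table.to_csv(outdir / "otu_table.tsv", sep="\t", index=False)
        self.relative_changes.to_csv(
            outdir / "relative_changes.tsv", sep="\t", index=False
        )
        self.biomass_stocks.to_csv(
            outdir / "biomass_stocks.tsv", sep="\t", index=False
        )
        self.fold_changes.to_csv(
            outdir / "fold_changes.tsv", sep="\t", index=False
        )
        for sid, tbl in self.group_proportions.items():
            tbl.to_csv(outdir / f"groups_{sid}.tsv", sep="\t", index=False)
        if self.newick is not None:
            (outdir / "tree.nwk").write_text(self.newick)


def _default_microscopy_specs(cfg: PipelineConfig) -> list[simulate.MicroscopySpec]:
    """Two-date microscopy scenario emulating a spring bloom contrast:
    a large phytoplankton increase driven by the bloom former, and a
    moderate microzooplankton response."""
    a, b = cfg.sample_a, cfg.sample_b
    return [
        # pre-bloom phytoplankton ~42 µg C/L rising ~34-fold at the peak,
        # driven almost entirely by the bloom former
        simulate.MicroscopySpec(
            taxon="Phaeocystis colonies", group="phaeocystis_colony",
            shape="sphere", abundance={a: 2.0e5, b: 7.2e7},
            dimensions=((6.0, 0.5),), trophic="auto",
        ),
        simulate.MicroscopySpec(
            taxon="Guinardia flaccida", group="diatom",
            shape="cylinder", abundance={a: 2.0e5, b: 6.0e5},
            dimensions=((60.0, 5.0), (8.0, 0.8)), trophic="auto",
        ),
        # microzooplankton ~6 µg C/L with a ~4-fold bloom response
        simulate.MicroscopySpec(
            taxon="Gyrodinium spirale", group="dinoflagellate",
            shape="prolate_spheroid", abundance={a: 1.5e3, b: 6.0e3},
            dimensions=((60.0, 4.0), (25.0, 2.0)), trophic="hetero",
        ),
        simulate.MicroscopySpec(
            taxon="Strombidium sp.", group="ciliate",
            shape="cone", abundance={a: 1.5e3, b: 6.0e3},
            dimensions=((40.0, 3.0), (30.0, 2.5)), trophic="hetero",
        ),
        simulate.MicroscopySpec(
            taxon="Heterotrophic nanoflagellates", group="nanoflagellate",
            shape="sphere", abundance={a: 1.0e6, b: 5.0e6},
            dimensions=((4.0, 0.4),), trophic="hetero",
        ),
    ]


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> RunReport:
    """Execute the full pipeline on synthetic data; see module docstring."""
    cfg = config
    cfg.validate()
    ledger = ReadLedger()

    # --- simulate ------------------------------------------------------
    db = simulate.generate_reference_db(
        cfg.n_families, cfg.genera_per_family, cfg.species_per_genus,
        seed=stage_seed(cfg.seed, "refdb")[1],
    )
    lineages = lca.parse_lineage_table(simulate.lineage_table(db))
    scheme = simulate.default_tag_scheme(
        [cfg.sample_a, cfg.sample_b], seed=stage_seed(cfg.seed, "tags")[1]
    )
    comm_a = simulate.generate_community(
        db, cfg.n_taxa, bloom_fraction=None,
        seed=stage_seed(cfg.seed, "community")[1], sample_id=cfg.sample_a,
        decay=cfg.community_decay,
    )
    # same taxa, bloom structure on the first: build B from A's taxon list
    bloom_id = comm_a.taxa[0][0]
    rest = [rid for rid, _ in comm_a.taxa[1:]]
    w = cfg.community_decay ** np.arange(len(rest))
    w = w / w.sum() * (1.0 - cfg.bloom_fraction)
    comm_b = simulate.CommunityProfile(
        sample_id=cfg.sample_b,
        taxa=tuple([(bloom_id, cfg.bloom_fraction)] + list(zip(rest, w.tolist()))),
        bloom_taxon=bloom_id,
    )
    length_model = simulate.LengthModel(
        full_fraction=cfg.full_length_fraction,
        min_length=cfg.truncation_min,
        max_truncated=cfg.truncation_max,
    )
    reads_a, truth_a = simulate.generate_reads(
        comm_a, db, scheme, cfg.n_reads_a, error_rate=cfg.error_rate,
        length_model=length_model, seed=stage_seed(cfg.seed, "reads_a")[1],
    )
    reads_b, truth_b = simulate.generate_reads(
        comm_b, db, scheme, cfg.n_reads_b, error_rate=cfg.error_rate,
        length_model=length_model, seed=stage_seed(cfg.seed, "reads_b")[1],
    )
    raw = [pio.RawRead(*r) for r in reads_a + reads_b]
    truth = pd.concat([truth_a, truth_b], ignore_index=True)

    # --- demultiplex ---------------------------------------------------
    by_sample, unassigned = pio.demultiplex(
        raw, scheme, primer_mismatches=cfg.primer_mismatches
    )
    ledger.record(
        "demux", "all", len(raw),
        sum(len(s) for s in by_sample.values()),
        {"unassigned": len(unassigned)},
    )
    qc_rows = []
    for sid, rs in by_sample.items():
        stats = pio.length_stats(rs)
        for row in stats.itertuples(index=False):
            qc_rows.append(
                {"sample": sid, "threshold": row.threshold,
                 "fraction_above": row.fraction_above}
            )
    qc = pd.DataFrame(qc_rows)

    # --- align + LCA ---------------------------------------------------
    group_proportions: dict[str, pd.DataFrame] = {}
    family_nodes = sorted(
        {f"{lca.ROOT}/{path[0][1]}" for path in lineages.values()}
    )
    for sid, rs in by_sample.items():
        hits = lca.align_reads(rs.reads, db)
        result = lca.assign_reads(
            hits, lineages, read_ids=[r.read_id for r in rs.reads],
            e_max=cfg.evalue, min_score=cfg.min_score,
            top_percent=cfg.top_percent, min_support=cfg.min_support,
        )
        ledger.record("lca", sid, len(rs), result.tree.total_reads())
        group_proportions[sid] = lca.summarize_groups(result.tree, family_nodes)

    # --- cluster + diversity ------------------------------------------
    all_reads = [r for rs in by_sample.values() for r in rs.reads]
    sample_of = {
        r.read_id: sid for sid, rs in by_sample.items() for r in rs.reads
    }
    otus = otu.cluster_greedy(
        all_reads, identity_threshold=cfg.identity, sample_of=sample_of,
        representative_min_len=cfg.representative_min_len,
    )
    validated, rejected = otu.validate_taxa(otus, min_reads=cfg.min_reads)
    ledger.record(
        "cluster", "all", len(all_reads),
        sum(o.size for o in validated),
        {"below_min_reads": sum(o.size for o in rejected)},
    )
    sample_ids = [cfg.sample_a, cfg.sample_b]
    avs = otu.abundance_vectors_from_otus(otus, sample_ids)
    diversity = pd.DataFrame(
        [dataclasses.asdict(otu.diversity_summary(avs[s])) for s in sample_ids
         if avs[s].N > 0]
    )
    otu_rows = []
    for o in otus:
        otu_rows.append(
            {"otu_id": o.otu_id, "centroid": o.centroid_id,
             "representative": o.representative_id, "size": o.size,
             "validated": o.size >= cfg.min_reads,
             **{f"n_{s}": o.per_sample.get(s, 0) for s in sample_ids}}
        )
    otu_table = pd.DataFrame(otu_rows)

    relative_changes = compare_samples(
        otu_table, f"n_{cfg.sample_a}", f"n_{cfg.sample_b}"
    )

    # map the bloom taxon to its OTU via the truth table + membership
    bloom_otu = None
    truth_map = dict(zip(truth["read_id"], truth["ref_id"]))
    best_overlap = 0
    for o in otus:
        overlap = sum(1 for m in o.members if truth_map.get(m) == bloom_id)
        if overlap > best_overlap:
            best_overlap, bloom_otu = overlap, o.otu_id

    # --- phylogeny on validated representatives ------------------------
    newick = None
    reps = [
        (o.otu_id, next(r.sequence for r in all_reads
                        if r.read_id == o.representative_id))
        for o in validated if o.representative_id is not None
    ]
    if len(reps) >= 3:
        aln = phylo.align_representatives(reps)
        if len(reps) >= 4:
            tree = phylo.bootstrap_support(
                aln, n_replicates=cfg.bootstrap_replicates,
                seed=stage_seed(cfg.seed, "bootstrap")[1],
            )
        else:
            ids, dmat = phylo.k2p_matrix(aln)
            tree = phylo.nj_tree(dmat, ids)
        newick = str(tree)

    # --- biomass -------------------------------------------------------
    table = simulate.generate_microscopy_table(
        _default_microscopy_specs(cfg), seed=stage_seed(cfg.seed, "microscopy")[1]
    )
    records, stocks = bm.community_biomass(table)
    fold = bm.fold_change_summary(stocks, by="category")

    report = RunReport(
        config=cfg, ledger=ledger, qc=qc, diversity=diversity,
        group_proportions=group_proportions, otu_table=otu_table,
        relative_changes=relative_changes, biomass_stocks=stocks,
        fold_changes=fold, newick=newick, bloom_taxon=bloom_otu, truth=truth,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def compare_samples(
    otu_table: pd.DataFrame, col_a: str, col_b: str
) -> pd.DataFrame:
    """Per-OTU normalized relative change between exactly two samples.

    `otu_table` must carry per-sample count columns `col_a` and `col_b`.
    Rows absent from the first sample are flagged "new", absent from the
    second "lost".
    """
    for col in (col_a, col_b):
        if col not in otu_table.columns:
            raise ValueError(f"missing per-sample count column {col!r}")
    N_A, N_B = int(otu_table[col_a].sum()), int(otu_table[col_b].sum())
    rows = []
    for row in otu_table.itertuples(index=False):
        n_a, n_b = int(getattr(row, col_a)), int(getattr(row, col_b))
        if n_a == 0 and n_b == 0:
            continue
        rc = otu.relative_change(n_a, n_b, max(N_A, 1), max(N_B, 1))
        rows.append(
            {"otu_id": row.otu_id, "n_A": n_a, "n_B": n_b,
             "R": rc.R, "status": rc.status}
        )
    return pd.DataFrame(rows)
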