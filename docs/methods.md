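# Methods

This note documents the models and procedures `planktag` implements,
the parameter defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Read structure and pre-processing

Reads are modeled as `[10-nt tag][TCAG key][forward primer][insert]`,
the layout of GS-FLX amplicon libraries with per-sample barcodes. The
default primers are the universal eukaryote pair 18S-82F
(`GAAACTGCGAATGGCTC`) and Ek-516r (`ACCAGACTTGCCCTCC`), which bracket
the ~470–480 bp V2–V3 region of the 18S rDNA.

Demultiplexing requires an exact match of the 10-nt tag and the 4-nt
key. Tags are long enough that exact matching is the conservative
standard; no error tolerance is applied. The forward primer may carry
mismatches (default budget 1, configurable) since primer-template
mismatches survive PCR. The reverse-primer complement, when it appears
at the 3′ end of a read, is trimmed; reads without it are kept, because
454 reads frequently terminate inside the insert. The 26-bp instrument
adapter is assumed already removed on the machine; a strip option is
not needed for synthetic data. No length floor is applied before
alignment — short reads are retained and simply tend to fail the
E-value filter downstream.

Demultiplexing is a partition: every input read lands in exactly one
sample bin or the unassigned bin, and the read ledger checks
`inputs = outputs + itemized drops` at every stage of the pipeline.

## Hit filtering and LCA assignment

Per read, alignment hits are filtered in two stages: (1) E-value ≤
1e-5 and bit score ≥ 5; (2) bit score within 1 percent of the best
score among the survivors of stage 1 (`score ≥ (100 − p)% · best`).
Ties at the boundary are retained. The min-score of 5 bits is far
below common practice but is kept as the default deliberately (it is
the setting this workflow is defined by); it is configurable, and the
assignment audit records how many hits each filter removed.

The read is then placed at the deepest taxonomy node shared by all
retained hits' lineages (naive LCA — no hit weighting). Reads with no
retained hits go to the "No hits" bin; reads whose retained hits map
only to references with no lineage below the root go to "Not
assigned". Hits legitimately spanning the whole tree place the read at
the root. Reads are conserved: assigned + Not assigned + No hits =
input, before and after min-support pruning.

Min-support pruning (default 1 = identity) moves reads off nodes whose
cumulative count is below the threshold, deepest nodes first, so reads
climb until they rest on a sufficiently supported ancestor. Totals are
conserved for any threshold.

Widening the top-percent window can only merge more lineages into the
LCA, so assignments move toward the root monotonically; this is
property-tested.

### Built-in aligner

So the taxonomy stage runs without an external BLAST, a small aligner
produces hits in BLAST outfmt-6 form: candidate references are screened
by shared exact 11-mers, the best candidates (default 8) are aligned
with an exact local (Smith–Waterman, affine-gap) alignment at BLASTN-like
scores (+2/−3, gap 5/2), and scores are converted to bit scores and
E-values with Karlin–Altschul-style parameters (λ = 0.625, K = 0.41 for
this score system; E = m·n·2^(−bit)). The k-mer screen replaces a
banded seed-and-extend: with desk-scale databases the exact local DP on
the screened candidates is both simpler and fast enough. An
`exhaustive=True` flag skips the screen and aligns against every
reference, serving as the slow oracle. E-values are approximate — this
aligner ranks hits and feeds the LCA filters; it does not reproduce
BLAST statistics exactly and is not meant to.

## Pairwise identity and OTU clustering

Percent identity between two reads is defined as `1 − d/L`, where `d`
is the minimal semi-global edit distance with the shorter sequence
aligned as a contiguous block inside the longer one (free end gaps on
the longer sequence) and `L` is the shorter length. Two reasons for
this definition rather than "matches over alignment columns": it is
unique (the column count of an optimal alignment depends on which
co-optimal path is chosen — `AC` vs `CA` has a two-substitution path
with identity 0 and an indel path with identity 1/3 at the same edit
distance), and it treats a truncated read as a fragment of its
full-length centroid, which is exactly the right semantics for
clustering 454 reads of very unequal length. The implementation uses
edlib's infix mode; tests verify exact agreement with an independent
full-DP oracle. Identity is symmetric by construction.

Greedy centroid clustering processes reads in decreasing length order
(ties broken by read id): the first read seeds the first centroid, and
each read joins the *first* centroid reached with identity ≥ 0.97,
else founds a new one. This mirrors greedy centroid-based methods
(Uclust-style) whose exact input ordering is tool-internal; the
length-descending, id-ascending order makes runs deterministic.
Because greedy assignment does not chain through intermediate reads,
it equals single-linkage components only when templates are well
separated (between-template divergence ≥ 2× the threshold radius and
within-template divergence < 3%); the clustering oracle test runs under
exactly those conditions.

Taxon validation keeps clusters with ≥ 3 member reads ("three
identical reads" is read as three reads in the 97% cluster — literal
sequence identity is not implied by a 97% radius). Each cluster's
representative is its longest member if that member exceeds 400 nt,
ties by read id; clusters with no member above the floor have none and
are excluded from tree building.

## Diversity statistics

For a sample with S OTUs, counts nᵢ, N = Σnᵢ and pᵢ = nᵢ/N:

- **Chao1**: `S + n₁²/(2·n₂)` where n₁ = singleton OTUs and n₂ = OTUs
  with **two reads or more**. That n₂ is nonstandard (classically n₂
  counts exact doubletons) but is the definition this workflow states;
  `classic_n2=True` switches to doubletons. When n₂ = 0 the
  bias-corrected fallback `S + n₁(n₁−1)/2` is returned and flagged.
  Chao1 ≥ S always, with equality iff n₁ = 0.
- **Shannon** `H' = −Σ pᵢ ln pᵢ`, natural log by default (the printed
  per-group values of the motivating survey, 1.5–2.8 over 5–28 taxa,
  are only consistent with natural log); base configurable.
- **Margalef** `d = (S−1)/ln N`, with d ≡ 0 at N = 1.
- **Simpson**: the Gini–Simpson complement `1 − Σ pᵢ²` by default;
  the dominance form `Σ pᵢ²` and the unbiased finite-sample form are
  selectable, since which variant a given survey prints is often
  ambiguous. None is asserted to equal any published value.
- **Rarefaction**: the analytic hypergeometric expectation
  `E[S_n] = Σᵢ (1 − C(N−nᵢ, n)/C(N, n))` (computed with log-gamma for
  stability), plus a seeded Monte-Carlo mode (subsampling without
  replacement) that must agree with the analytic mode within sampling
  error; both are exposed because published curves rarely state which
  was used.
- **Relative change** between dates A and B for taxon i:
  `R = (n_iB/N_B)/(n_iA/N_A)`. R is the depth-normalized fold change;
  `n_iA = 0` flags a "new" taxon (R undefined, reported as ∞),
  `n_iB = 0` a "lost" one (R = 0). `R(A→B)·R(B→A) = 1` for positive
  counts.

## Phylogenetics

**K2P distance** with pairwise deletion: columns where either row has
a gap or ambiguity are excluded per pair (not complete deletion, which
discards far more signal on gappy 454 alignments; complete deletion
can be had by pre-filtering columns). With transition proportion P and
transversion proportion Q, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`.
Saturated pairs (either log argument ≤ 0) are reported as a flagged
ceiling of 10.0 substitutions/site rather than an error, so one
saturated pair does not abort a matrix.

**Neighbor joining** is the classical Saitou–Nei agglomeration with
the Q-criterion and standard branch-length formulas, returning an
unrooted tree as a trifurcating root. On additive matrices the
reconstructed path lengths match the input within 1e-9 (tested, and
cross-checked against an independent NJ implementation). Negative
branch lengths — a normal NJ artifact on noisy matrices — are clamped
to zero with the deficit moved to the sister branch, preserving the
pair's path length.

**Bootstrap**: replicate r resamples alignment columns with
replacement using an RNG seeded by (seed, r), so replicates are
reproducible and independent of execution order. Support of each
internal edge of the full-data tree is the fraction of replicate trees
containing the same bipartition (splits canonicalized on the smaller
side). The workflow default is 1000 replicates; validation runs use
25–100 because support determinism and the separation of a clean
two-clade signal are already decidable there, and the replicate count
is a linear cost dial that does not change the code path.

**Progressive alignment** is a deterministic center-star: the center is
the sequence with the highest summed pairwise identity, every other
sequence is globally aligned to it with affine gaps, and the pairwise
alignments are merged column-wise ("once a gap, always a gap"). This
replaces external MSA heuristics; it is exact for the pairwise case,
never loses residues, and its column count is at least the longest
input. It does not attempt the alignment quality of a full progressive
profile aligner and is not tested for one — NJ/K2P on its output is
the piece under test.

## Biomass

Biovolume comes from the nearest geometric solid — sphere πd³/6,
prolate spheroid πLw²/6, cylinder πw²L/4, cone πw²L/12, and a
cylinder capped by two half-spheres π w²(L−w)/4 + πw³/6. Carbon per
cell:

- ciliates: 0.190 pg C µm⁻³ × V (the 190 fg C µm⁻³ convention);
- dinoflagellates: 0.760·V^0.819 pg C;
- phytoplankton and other protists: configurable a·V^b, defaulting to
  the Menden-Deuer & Lessard coefficients — diatoms (0.288, 0.811),
  non-diatom protists (0.216, 0.939). The colony-forming bloom taxon
  and heterotrophic nanoflagellates use the non-diatom power law unless
  overridden; both are pluggable because colony carbon is usually
  derived from dedicated colony biovolume relationships that a survey
  calibrates separately.

Biomass is `abundance (cells L⁻¹) × cell carbon (pg) × 10⁻⁶ µg/pg`,
exactly; group stocks sum exactly to the grand total, and biomass is
linear in abundance and monotone in volume for every registered
conversion (tested). Survey fold change is max/min over dates per
group, rounded to the nearest integer for reporting; any zero stock
makes the ratio undefined and flagged rather than infinite.

## Synthetic data: what it emulates, what it does not

The generator exists so every stage has inputs with known truth.

- **Reference database**: one ancestral ~500-nt sequence mutated down
  a family→genus→species tree at per-branch rates of half the target
  divergence (defaults ~2% within genus, ~8% within family, ~15%
  between families). This gives LCA and 97% clustering the separation
  structure they need. Lineages are three ranks deep
  (family/genus/species); the taxonomy tree adds a synthetic root.
- **Communities**: geometric rank-abundance series (default decay
  0.85), optionally with a bloom taxon pinned to an exact fraction
  (0.9 by default, emulating a bloom former at >90% of biomass) and
  the series renormalized to the remainder.
- **Reads**: multinomial taxon sampling, per-base substitution errors
  (default 0.5%), and a two-component length-attrition model — full
  length with probability 0.40, else truncation to a uniform length on
  [50, 400). With ~470-nt inserts this lands ~75% of reads above
  200 nt and ~40% above 400 nt, the attrition regime of one-run 454
  titanium data. A geometric truncation tail was considered and
  rejected: it cannot hit both benchmark fractions without an
  arbitrary cap. Truth tables (read → source reference) are always
  produced.
- **Microscopy tables**: one row per taxon and date with lognormal,
  mean-preserving dimension jitter (sd = 0 reproduces the mean
  exactly). The pipeline's default scenario contrasts two dates with a
  ~34-fold phytoplankton and ~4-fold microzooplankton stock increase.

Deliberately not emulated: chimeras, homopolymer indels (point
substitutions exercise the same downstream logic), quality scores,
reverse-complement reads (the protocol reads from the tagged end), and
any real accession's read-name scheme. Consequently, passing tests
demonstrate the correctness of the algorithms under clean, known-truth
conditions — not robustness to PCR chimeras, indel-rich homopolymer
noise, or real database incompleteness.

A related, instructive artifact: under heavy truncation, a read's
*relative* error load is unbounded (2 errors in a 50-nt read is 4%
divergence), so error-rich truncated reads of a dominant taxon can
seed satellite OTUs and inflate richness — the same inflation
reported for pyrosequencing surveys generally. The template-recovery
validation therefore runs on full-length reads, where within-taxon
divergence stays below the 3% clustering radius; the attrition model
stays on everywhere else.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage substreams from the single config seed via stage-name CRCs,
so a run is byte-reproducible and stages can be re-run independently.
Validation problem sizes are chosen so the full suite exercises every
code path at desk scale: reference databases of 8–20 sequences,
80–400 reads per scenario, 100–1000 Monte-Carlo or bootstrap
replicates. Statistical assertions use 3σ binomial or 3-standard-error
bands around the known truth.

## Known limitations

- The built-in aligner's E-values are calibrated approximations;
  rankings are reliable, absolute E-values are not BLAST's.
- Greedy centroid clustering is order-dependent by nature; the
  deterministic ordering here is a convention, not a claim about any
  specific external tool's ordering.
- The center-star aligner is adequate for near-identical 454
  representatives; divergent sequence sets deserve a real MSA tool.
- The LCA is unweighted; low-complexity reads with many tied hits
  generalize quickly toward the root.
- Published index values from real surveys cannot be reproduced
  without the underlying per-taxon read counts; the package validates
  its statistics on synthetic data and closed-form cases instead.
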