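# Methods

## Problem setting

Seed lignans derive from (+)-pinoresinol, formed when two coniferyl
alcohol units are oxidatively coupled under the stereochemical control
of a dirigent protein.  The oxidase is a peroxidase (POD) or laccase
(LAC), but these families are large and mostly unrelated to lignan
biosynthesis, so the synthase must be narrowed down indirectly: a true
pinoresinol synthase should be conserved across varieties (core
pan-genome), seed-preferential, expressed from early seed development,
and its trajectory over days after anthesis (DAA) should track the
known rise-and-fall of pinoresinol accumulation, which peaks in
mid seed filling and declines toward maturity (~30 DAA).  This package
turns that argument into an auditable, parameterized screen plus the
surrounding census, duplication, promoter and qPCR analyses.

## Family census

Domain hits come from `hmmsearch --domtblout` tables (PF00141 for
peroxidases, TIGR03390 for laccases).  A hit is accepted iff
`full_evalue <= 1e-5` **and** `dom_ievalue <= 1e-5`; both comparisons
are inclusive, matching the reporting semantics of `hmmsearch
-E/--domE`, and the boundary is fixed so tests can pin it.  A second,
independent domain-scan table (PfamScan-style) must contain the
family's named domain (`peroxidase` / `laccase`) or the gene is demoted
to `rejected_spurious`.  Multiple domain rows for one gene merge into a
single assignment that keeps every hit as evidence.

Orthogrouping is deliberately simple: single-linkage connected
components of the similarity graph restricted to edges with
`score >= min_score` (default 50).  This replaces a full
MCL-on-normalized-scores orthology inference because the pipeline uses
orthogroups only for a presence/absence census; the clustering function
is a small, pluggable unit and its output is checked against a
transitive-closure oracle in the tests.  "Core" means at least one
member in every variety (not single-copy); "specific" means exactly
one variety.  Count summaries use the arithmetic mean and the n−1
sample standard deviation, with integer rounding applied only at the
reporting layer (six counts of 56, 48, 45, 42, 40, 35 report as
44 ± 7).

## Duplication and synteny

Genes are ranked 1..n along each chromosome by start coordinate (ties:
end, then gene id); all downstream logic uses ranks, so assembly
coordinate scales are irrelevant.  Collinear blocks are chained per
chromosome pair by a longest-chain dynamic programme over anchor rank
pairs: side-A ranks strictly increase, side-B ranks strictly increase
("same" orientation) or strictly decrease ("inverted"), and
consecutive-anchor rank gaps are bounded by `max_gap` (default 25) on
both sides.  Chains are extracted greedily, longest first, removing
used anchors, until no chain reaches `min_anchors` (default 5).
Determinism is pinned down fully: chains score by anchor count (unit
weights); at equal length "same" orientation wins over "inverted"; and
within an orientation the lexicographically smallest maximum-length
chain of (rank_a, rank_b) pairs is taken, reconstructed from a
longest-chain-starting-here table by greedy forward selection.  This
exact rule is what the exhaustive-enumeration oracle in the tests
reproduces.  Blocks are reported sorted by chromosome pair and first
side-A rank.

Paralog pairs classify as **tandem** iff on the same chromosome with
rank difference ≤ 1 (consecutive homologs, the MCScanX-style
convention; configurable), else **segmental** iff the pair is an anchor
of an intragenomic block, else **dispersed**.  Proximal/WGD subclasses
are not distinguished — the analyses this supports only contrast
tandem vs segmental.  The cross-species synteny fraction counts family
genes appearing as a side-A anchor in at least one cross-species block;
the percentage is rounded to the nearest integer for reporting.

## The expression screen

Inputs: an FPKM matrix over three panels (multi-organ; high/low-oil
seed time series; white/black seed-color time series), a kinetic
profile of seed pinoresinol content, and classified orthogroups.  The
filters, in order, with their tunable thresholds (`ScreenConfig`):

| stage | rule | parameter (default) |
|---|---|---|
| 1 seed preference | mean seed FPKM ≥ `seed_fold` × best non-seed organ mean, and ≥ `min_expr` | `seed_fold` 2.0, `min_expr` 1.0 FPKM |
| 2 early oil panel | FPKM ≥ `min_expr` at every variety's earliest sampled stage | — |
| 3 seed-color panel | FPKM ≥ `min_expr` at the white variety's stages ≤ `color_max_stage` DAA | `color_max_stage` 8 |
| 4 kinetic rule | peak strictly before the last stage; mean FPKM over stages ≥ `decline_stage` ≤ `decline_ratio` × peak; CV across stages ≥ `flat_cv` | `decline_stage` 23, `decline_ratio` 0.7, `flat_cv` 0.3 |
| 5 core membership | gene's orthogroup classed core | — |

Design choices worth recording:

- "Preferential seed expression" is quantified as 2-fold over the
  maximum non-seed organ with a 1-FPKM floor.  The source analyses
  state the criterion qualitatively; the numbers live in `ScreenConfig`
  and are echoed in every report header.
- Stage 3 requires *presence* in the white (lignan-rich) variety, not
  dominance over the black one: a constitutively expressed gene is
  meant to survive this stage and die only on the kinetic rule, which
  is exactly how the screen's known confounder behaves.
- The decline anchor of 23 DAA reflects the observation that candidate
  trajectories have turned down about a week before maturity.
- The Pearson correlation between a gene's white-variety trajectory and
  the pinoresinol profile is reported in the audit record but not
  thresholded — the kinetic argument is qualitative, and the pass/fail
  criteria (peak position, decline, non-flatness) capture it more
  robustly than an arbitrary correlation cutoff would.
- Replicates are averaged (arithmetic mean of FPKM) before filtering;
  the emulated public datasets are single-replicate per stage, so this
  is a generalization.
- All five stage booleans are evaluated for every gene (cheap), so the
  report is a complete audit trail; the final set is their conjunction,
  which is equivalent to sequential filtering.

Monotonicity holds by construction: raising `min_expr`, `seed_fold` or
`flat_cv`, or lowering `decline_ratio`, can only shrink the final set.

## Promoter regulation

Promoters are the 2 kb upstream of the annotated gene start — the
annotation does not distinguish transcription from translation start,
so the gene start anchors the window.  Plus strand: bases
[start−2000, start−1], truncated at position 1; minus strand: bases
[end+1, end+2000] reverse-complemented; output is 5'→3' relative to
the gene.  Scanning is exact IUPAC-degeneracy matching (no PWM
log-odds) on both strands; an `N` in the sequence matches nothing
(conservative), and minus-strand hits are reported at the plus-strand
coordinate of the match start.  A small built-in element table
(PlantCARE-style names, five functional categories) serves the
simulator and examples; real analyses should supply their own table —
the web lookup services the field commonly uses are versioned and
remote, and a local table keeps runs reproducible.

TF enrichment is the upper-tail hypergeometric test per family
(`P[X ≥ k]` with population N = background genes, K = bound genes in
background, n = target set) with Benjamini–Hochberg adjustment across
families, the standard over-representation convention.

## qPCR validation

Relative expression is 2^−ΔΔCT with amplification efficiency fixed at
2 and no dilution-series correction.  Technical replicates aggregate
as the arithmetic mean of Ct (standard ΔΔCT practice).  ΔCT subtracts
the reference gene within each sample; ΔΔCT subtracts the calibrator
sample within each gene, so the calibrator column is exactly 1 and the
whole table is invariant to adding a constant to every Ct.  Concordance
with RNA-seq is the squared Pearson correlation between log2 relative
expression and log2(FPKM + 1) over shared (gene, sample) points; zero
variance on either axis is reported as NaN rather than forced to a
number.

## The synthetic-data generator

The generator emulates the *structure* of the study system so that
planted truth is recoverable exactly at defaults, while making no claim
to reproduce real magnitudes:

- **Pan-genome**: 6 varieties; 65 POD + 42 LAC orthogroups with core
  fraction 0.625; one gene per present variety, plus planted duplicates
  in the reference variety (18 segmental + 1 tandem POD pairs, 20
  segmental LAC pairs, mirroring the real duplication pattern, plus two
  dispersed pairs).  Reference-variety inclusion of non-core
  orthogroups alternates deterministically so the reference annotation
  size is stable (> 80 expression genes in every run).
- **Genome layout**: 8 chromosomes; segmental blocks occupy one
  adjacent chromosome pair each so planted blocks can never merge or
  interfere; a handful of anchors below the minimum block size are
  added as non-chainable noise.  Cross-species anchors cover ~37% of
  POD and ~54% of LAC reference genes, packed so every participating
  chromosome carries at least one viable block.
- **Domain hits**: true members draw full E-values from 10^U(−30,−8);
  decoys from the configured range strictly above 1e-5 (the threshold
  filter removes exactly them); "spurious" genes pass the threshold but
  lack the family domain in the scan table, exercising the
  verification step.
- **Expression**: FPKM = archetype mean × exp(N(0, `noise_sd`)),
  multiplicative lognormal noise (default sd 0.15) — the standard
  positive-valued expression noise model, with an exact zero-noise
  limit.  Candidate seed trajectories are
  `6 + A·exp(−ln²(s/18)/(2·0.18²))` with per-gene amplitude
  A ~ U(40, 80): sampled peak at 20 DAA, clear decline by 23–30 DAA,
  and ~6 FPKM at the earliest stages (≥ 4× the 1-FPKM floor, so
  recovery is robust to the planted noise).  Confounders: one flat
  seed-preferential gene (20 FPKM at all stages), late-peaking genes
  (peak 29 DAA, near-silent early), organ-dominant genes and ubiquitous
  background genes.  The real studies do not print candidate FPKM
  magnitudes; these effect sizes are package choices, documented here,
  not claims about the organism.
- **Pinoresinol profile**: the published accumulation data are
  figure-derived and not printed, so a parametric lognormal-shaped
  curve peaking at 20 DAA stands in.  All tests of the kinetic rule are
  against planted truth, not against the literature curve.
- **Ct tables**: Ct = 35 − log2(FPKM + 1) + N(0, `ct_sd`), three
  technical replicates.  The reference housekeeping gene's Ct is
  computed from its across-sample mean FPKM, so it is exactly constant
  at `ct_sd` = 0 — the housekeeping assumption made explicit.
- **Determinism**: every stream derives from `rng_seed` through fixed
  seed sequences; serialization uses fixed orderings and float formats,
  so identical configurations give byte-identical files.

What the generator does *not* emulate — read-level sampling noise,
length/GC bias in FPKM, genuine sequence evolution, assembly errors,
batch effects between the three expression panels — bounds what
passing tests show: they demonstrate that the implemented rules are
correct and that the screen's logic recovers a signal of the planted
shape, not that the thresholds are optimal for any real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on 20
simulated pan-genomes of ~130 reference genes × 74 samples each
(seconds per run), 200 random chaining instances of ≤ 10 anchors
against exhaustive enumeration, hypergeometric enumeration up to
N = 30, and motif scans of 5-kb random sequences — sizes chosen so the
oracles stay exact and exhaustive.  Floating-point comparisons against
oracles use 1e-10..1e-12 absolute tolerances; the orthogroup id order,
block order and report row order are all deterministic so equality
checks are exact.

## Known limitations

- Single-linkage orthogrouping will chain families through promiscuous
  similarity edges; with curated input graphs this is the intended
  census behavior, but it is not a substitute for full orthology
  inference on raw all-vs-all scores.
- The chainer's greedy longest-first extraction is deterministic and
  oracle-checkable but not globally optimal as a block cover; with
  larger gap allowances a single long chain can absorb anchors that two
  separate blocks would otherwise claim.
- The screen consumes FPKM as given; no cross-panel normalization is
  attempted beyond the log transform, matching how the emulated
  datasets were originally analyzed.
- Tandem classification uses rank adjacency only; interleaved
  non-family genes are invisible when the annotation is restricted to
  family members.
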