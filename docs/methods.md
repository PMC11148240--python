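# Methods

## Problem setting

Mismatch-repair-deficient tumors accumulate indels in microsatellites.
A coding indel whose size is not a multiple of 3 shifts the reading frame
and produces a novel downstream protein. Because indel sizes congruent
modulo 3 shift the frame identically, the downstream product depends only
on the size class (3n+1 or 3n+2) and not on the indel's exact size or its
position within a tract — the sequence 3' of the tract is unchanged by any
in-tract edit, and the codon grid over that sequence is fixed by the net
shift modulo 3. The package therefore represents the entire frameshift
spectrum at a locus by two canonical deletions: 2 bp (class 1, all 3n+1
indels) and 1 bp (class 2, all 3n+2 indels). This equivalence is not
assumed: it is exercised as a property test and re-derived by the
acceptance script against literal edit-and-translate oracles.

## Microsatellite model

A tract is a maximal run of whole units of a primitive 1–5 bp motif on the
plus strand (tract spans are strand-symmetric; coding orientation is
handled downstream). Defaults: homopolymers must exceed five units
(min 6), motifs of 2–5 bp need at least three units; all minima are
configurable because repeat-catalog dialects differ (some use ≥ 5 for
homopolymers). Determinism rules: only whole units count (trailing partial
units are excluded from the span); a tract is anchored at its leftmost
attainable start; after emitting a tract, scanning for that motif length
resumes at the first base after it, so same-motif-length tracts never
overlap; non-primitive motifs are suppressed (an `A` run is never also an
`AA` tract); tracts containing N are never produced. The implementation
scans a period-k match profile in O(n) per motif length; the test suite
holds it equal to an exhaustive per-start brute-force scanner on random
and low-complexity sequences.

One subtlety: whole-unit spans are not strictly mirror-symmetric — a
7-base `CACACAC` region anchors as `CA`×3 on the plus strand but `GT`×3 at
the mirrored offset on the reverse complement. The strand-covariance
property is therefore stated (and tested) on the enclosing maximal
period-k regions, which are exactly mirror-symmetric.

## Variants and peptides

For each (locus, transcript) pair where the tract has ≥ 3 bases inside the
CDS, the two canonical deletions are generated. For peptide generation the
deletion removes the last `del_len` bases of the tract's in-CDS portion in
coding orientation (placement is irrelevant by the equivalence above); for
VCF emission the deletion is independently normalized — shifted to its
leftmost equivalent placement against the genome and anchored on the
preceding base — so the same locus always yields the same normalized
variant key regardless of strand.

Junction handling: the wild-type/mutant boundary region inside and near
the tract depends on the exact indel, so the reported peptide starts at
the first mutant codon all three of whose bases lie strictly 3' of the
tract in mutant coordinates. The junction-included tail is retained as an
optional output column for users who want it. Translation (standard code,
table 1) continues into the annotated 3' UTR; if no stop is reached by
transcript end the peptide is kept and flagged `non_stop`, since
frameshifts routinely read through the annotated stop. A frameshift whose
first post-tract codon is a stop yields no record. Tracts spanning splice
junctions are processed on the spliced coding sequence, where the frame
lives. Identical peptide strings are collapsed to one record with merged,
sorted provenance.

Transcripts whose annotated CDS length is not divisible by 3 are read and
flagged but excluded from peptide generation; CDS containing N is flagged
untranslatable. The CDS is taken exactly as annotated (no assumption about
stop-codon inclusion beyond what the annotation states).

## Epitope enumeration and filtering

Window lengths default to 8–11 aa (Class I) and 15 aa (Class II),
configurable — standard lengths for the MHC classes rather than values
fixed by the upstream catalogue. The shipped allele panels hold 27 Class I
and 27 Class II high-frequency HLA alleles (Class II DQ/DP entries are
alpha/beta pairs). Predictors implement a minimal contract (`supports`,
`predict`); scores from algorithms that fail or do not support a
class/length are recorded as missing, never imputed as zero, and
aggregates are computed over observed scores only. The inclusion rule is
best (minimum) IC50 < 50 nM in any algorithm; the median is stored
alongside so that median-based summaries (e.g. a 500 nM median cut) can
also be produced. The built-in toy predictor maps a stable 64-bit hash of
(epitope, allele, algorithm) log-uniformly onto [1, 50000] nM: fully
deterministic across processes, platform-independent, and spanning the
dynamic range of real predictors. Candidates are deduplicated by
(epitope string, allele), with all source peptides and offsets retained.

## Annotation

Evidence joins are left joins: every candidate is kept, matches are
appended in deterministic (source, key) order. Variant keys use the same
left-aligned anchored normalization as the emitted VCF, so external
variant tables join exactly. Peptide-keyed (IEDB-like) matching is exact
string equality — no substring or MHC-restriction matching.

Differential expression uses a two-sided Wilcoxon rank-sum test per gene
between normal and tumor groups, Benjamini–Hochberg step-up adjustment
over all tested genes, and a flag at adjusted p < 0.05. The rank-sum test
is this package's choice of a robust two-group default; the adjustment and
threshold are the catalogue's stated rule. Genes with zero variance across
all samples are untested and unflagged. BH is implemented directly (sort
ascending, multiply p(i) by m/i, cumulative minimum from the largest rank,
cap at 1) and cross-checked against statsmodels in the test suite.

The top-expression filter ranks genes by their mean expression within the
chosen cohort (median available by option), keeps the top fraction, and
retains all ties at the cutoff value. Expression units are whatever the
input matrix carries (TPM-like values in the fixtures); only ranks and
within-gene group comparisons are used.

## Store and queries

A single-file SQLite store replaces a client/server stack: peptides,
per-source provenance, candidate aggregates, raw scores, evidence and
expression in indexed tables, with a deterministic build (row-set equality
across rebuilds from identical inputs). `search` requires at least one
filter (unbounded queries are refused) and orders by (gene, epitope,
allele); `best` defaults to the median statistic and ranks ascending,
ascending-by-statistic being this package's choice of ranking. The
coverage check matches validated peptides exactly against the epitope
column by default; the store also exposes the full-peptide universe so
that frameshift-peptide lists (as in the fixture truth tables) can be
checked the same way.

## Synthetic fixtures

The generator emulates the pipeline's study conditions at desk scale: a
genome of one or two chromosomes carrying 6–16 single-transcript genes
(1–3 exons, mixed strands, 3' UTRs), with a planted tract list spanning
motif lengths 1–5 across CDS, intronic and intergenic placements. The
small preset plants seven tracts (five coding: A×7, AC×4, AGC×3, AAAG×3,
AAGGC×3; one intronic; one intergenic). Background and intron sequence is
made repeat-free constructively: accidental tracts meeting the thresholds
are broken by single-base patches — codon-aware inside CDS so the
wild-type frame never gains a stop — until a full scan returns exactly
the planted loci. Planted tracts carry guard flanks (left flank differs
from the motif's last base, right flank from its first) so maximality and
anchoring are exact, which makes all counting assertions exact rather than
probabilistic. Truth peptides are computed from the final patched sequence
by an independent edit-and-translate oracle (explicit codon-table loop).

The expression generator draws log-normal values (per-gene log-mean
~ N(log 100, 1), noise sd 0.5 on the log scale) for 20 normal + 20 tumor
samples over 50 genes, shifting 5 planted genes 4-fold in tumors —
an effect size and sample size at which rank-sum/BH recovery is
essentially certain, so the power check is sharp. Evidence tables cover a
configurable fraction of variant keys and epitopes with keys normalized
identically to the pipeline's.

What the fixtures do not emulate: realistic human gene structure and
lengths, interrupted/imperfect repeats, motif lengths > 5, realistic
allele frequencies or linkage, sequencing noise, and real binding-affinity
landscapes (the toy predictor's scores are uniform on the log scale, so
retention rates are far higher than with trained predictors). Passing
tests therefore demonstrate the correctness of the algorithmic contracts,
not predictive performance on real genomes.

## Numerical and design notes

- Coordinates are 1-based closed (GFF convention) internally; BED export
  is 0-based half-open; VCF emission is anchored and left-aligned.
- Problem sizes in tests and the acceptance script (300-mer scan
  sequences, 200 equivalence tracts, 400-epitope score batches, 200-gene
  null matrices over 20 seeds) are chosen to make each check exhaustive at
  desk scale while keeping a full run in seconds.
- The genome-wide catalogue numbers of a full human run (tens of millions
  of loci) are functions of GRCh38 and a specific annotation release and
  are out of scope here; the per-locus counting identity (two variants per
  coding locus/transcript pair) is asserted instead. A published
  per-locus "potential mutations" figure of 3× the coding-locus count
  does not follow from the two-variant representation; this package emits
  exactly 2 per pair and documents the identity it satisfies.
- Deduplication makes the peptide set invariant to whether variants are
  generated per transcript or per gene.
- `search`/`best` pagination (limit/offset) and ordering are explicit and
  deterministic so query results are stable across invocations.

## Known limitations

- No proteasomal-processing, binding-stability or foreignness scoring;
  columns for externally supplied values are reserved in the store.
- Junction-spanning epitopes are excluded by design.
- Only perfect (uninterrupted) repeats are detected.
- The annotation file is treated as authoritative for what counts as
  protein-coding; no transcript-biotype reasoning is performed.
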