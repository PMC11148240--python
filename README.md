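# msneoforge

Frameshift neoantigen discovery from coding microsatellites.

Tumors with mismatch-repair deficiency (dMMR) accumulate insertions and
deletions in microsatellites — tracts of tandemly repeated 1–5 bp motifs.
When such an indel falls in a coding tract and its size is not a multiple
of 3, the reading frame shifts and the ribosome produces an entirely novel
downstream protein sequence: a rich source of tumor-specific neoantigens
for MSI-high cancers and Lynch-syndrome carriers. `msneoforge` builds a
queryable catalogue of these candidate neoantigens directly from a genome
and its gene models, for immunologists and computational biologists
designing vaccines or screening epitope panels.

## Method

1. **Scan** the genome for maximal primitive-motif repeat tracts:
   homopolymer runs of more than five units, and ≥ 3 whole units for 2–5 bp
   motifs; keep tracts overlapping annotated CDS.
2. **Represent all frameshifts by two canonical deletions.** Indels of
   sizes congruent modulo 3 shift the frame identically, so every
   frameshifting indel in a tract belongs to one of two classes — 3n+1 or
   3n+2 shifts (n ∈ ℤ). A 2-bp deletion (3n+1, n = −1) and a 1-bp deletion
   (3n+2, n = −1) at each locus cover both classes exactly. Variants are
   emitted as left-aligned, anchored VCF deletions.
3. **Translate the mutant transcript** (CDS + 3' UTR) and report the
   *junction-excluded* downstream peptide: translation from the first
   codon lying entirely 3' of the tract in mutant coordinates, to the
   first stop. Identical peptides from different loci/transcripts are
   deduplicated with merged provenance.
4. **Enumerate MHC epitope windows** (8–11-mers for Class I, 15-mers for
   Class II) and score them against default panels of 27 Class I and 27
   Class II high-frequency HLA alleles through a pluggable predictor
   contract. A candidate (epitope, allele) pair is retained when its best
   predicted affinity is IC50 < 50 nM in **any** algorithm; best/median/
   mean aggregates, terminal residues and the GRAVY score (mean
   Kyte–Doolittle hydropathy) are recorded.
5. **Annotate and store**: left joins against dbSNP-like / ClinVar-like /
   IEDB-like evidence tables, differential-expression labels
   (two-sided rank-sum test, Benjamini–Hochberg adjusted p < 0.05) from a
   tumor/normal expression matrix, all persisted in a single-file SQLite
   store served by two query modes — `search` (conjunctive filters) and
   `best` (per-allele ranking below an affinity cutoff, optionally
   restricted to the top expression fraction of a cohort).

External binding predictors are deliberately out of scope; the built-in
deterministic toy predictor (a stable hash mapped log-uniformly onto
[1, 50000] nM) exercises every contract at desk scale, and real predictor
adapters plug into the same interface.

## Worked example

Everything runs on a self-contained synthetic fixture — a small genome
with planted microsatellites whose expected frameshift peptides are known
in advance:

```
$ msneoforge --seed 1 run-all --preset small --out demo
microsatellites_genome        7
microsatellites_coding        5
coding_locus_transcript_pairs 5
canonical_variants            10
unique_frameshift_peptides    10
class_i_candidates            7978
class_ii_candidates           1303
truth_peptides_present        10
truth_peptides_missing        0
```

Seven tracts were planted (five in CDS, one intronic, one intergenic);
the scanner finds exactly those seven, the five coding ones yield
2 × 5 = 10 canonical deletions and 10 unique downstream peptides, and the
store's coverage check finds every expected peptide present. Querying the
best HLA-A\*02:01 binders below a 30 nM median affinity, restricted to the
top 20% expressed genes of the `demo` cohort:

```
$ msneoforge best --store demo/store.sqlite --allele "HLA-A*02:01" \
      --cutoff 30 --cohort demo --top-fraction 0.2 | head -3
epitope      allele       gene   best    median  mean    gravy
PAHFGLLTSTR  HLA-A*02:01  GENE1  1.61    1.64    497.3   0.027
TRTARGPV     HLA-A*02:01  GENE4  1.00    1.97    11.3    -0.800
```

Rows are ranked by ascending median IC50; every row satisfies the cutoff
and the expression restriction.

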