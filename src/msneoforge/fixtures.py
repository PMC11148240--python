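"""Synthetic genomes, expression matrices and evidence tables with planted truth.

Every stage of the pipeline is testable without downloads: the generator
emits a small genome FASTA plus GTF whose microsatellite content is exactly
the planted tract list, an expression matrix with planted differentially
expressed genes under a log-normal noise model, and evidence tables keyed
identically to the pipeline's variants and epitopes.

Construction guarantees:

* background and intron sequence is repeat-free by construction -- accidental
  tracts meeting the scan thresholds are broken by targeted single-base
  patches (codon-aware inside CDS, never creating a stop codon in the
  wild-type frame) until a full scan of each chromosome returns exactly the
  planted loci;
* planted tracts are flanked by guard bases that cannot extend the tract by
  a unit or shift its anchor, so maximality and coordinates are exact;
* the truth table lists, per planted coding tract, the two expected
  junction-excluded downstream peptides computed by a literal edit-and-
  translate oracle over the final sequence (codon-table loop, independent
  of the pipeline's translation path);
* all randomness flows from one seed; identical seeds give identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import GenomeSequence
from .repeat_scan import MicrosatelliteLocus, ScanParams, scan_sequence

logger = logging.getLogger("msneoforge")

_CODON_TABLE = unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)  # {"TAA", "TAG", "TGA"}
_FORWARD = dict(_CODON_TABLE.forward_table)
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PlantedTract:
    motif: str          # coding orientation for CDS tracts, plus strand otherwise
    unit_count: int
    placement: str      # "CDS" | "intron" | "intergenic"

    @property
    def tract_len(self) -> int:
        return len(self.motif) * self.unit_count


@dataclass(frozen=True)
class ExpressionDesign:
    n_normal: int = 20
    n_tumor: int = 20
    n_genes: int = 50
    n_de_genes: int = 5
    effect_size: float = 4.0     # multiplicative shift in tumor samples
    sigma: float = 0.5           # log-normal noise sd
    cohort: str = "demo"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_chromosomes: int = 1
    genes_per_chrom: int = 6
    planted: tuple[PlantedTract, ...] = (
        PlantedTract("A", 7, "CDS"),
        PlantedTract("AC", 4, "CDS"),
        PlantedTract("AGC", 3, "CDS"),
        PlantedTract("AAAG", 3, "CDS"),
        PlantedTract("AAGGC", 3, "CDS"),
        PlantedTract("T", 6, "intron"),
        PlantedTract("GA", 3, "intergenic"),
    )
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)
    evidence_fraction: float = 1.0


def preset(name: str, seed: int = 1) -> FixtureSpec:
    """Named fixture presets: 'small' (default sizes) and 'medium'."""
    if name == "small":
        return FixtureSpec(seed=seed)
    if name == "medium":
        extra = (
            PlantedTract("C", 8, "CDS"),
            PlantedTract("AT", 5, "CDS"),
            PlantedTract("CAG", 4, "CDS"),
            PlantedTract("G", 6, "intergenic"),
        )
        return FixtureSpec(
            seed=seed,
            n_chromosomes=2,
            genes_per_chrom=8,
            planted=FixtureSpec().planted + extra,
        )
    raise ValueError(f"unknown preset {name!r}")


# --------------------------------------------------------------------------
# truth oracle: literal string edit + codon-table translation
# --------------------------------------------------------------------------

def oracle_translate(nt: str) -> tuple[str, bool]:
    """Codon-by-codon translation with an explicit table lookup."""
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in _STOPS:
            return "".join(aa), True
        aa.append(_FORWARD[codon])
    return "".join(aa), False


def oracle_downstream(full_seq: str, tract_cstart: int, tract_cend: int,
                      indel: int, at: int | None = None,
                      insert_base: str | None = None) -> tuple[str, bool]:
    """Edit-and-translate oracle for an arbitrary in-tract indel.

    ``indel`` < 0 deletes ``-indel`` bases ending at coding position ``at``
    (default: tract end); ``indel`` > 0 inserts ``indel`` copies of
    ``insert_base`` after position ``at``.  Returns the junction-excluded
    downstream peptide (translation of the standard codon grid from the
    first codon entirely 3' of the tract in edited coordinates) and a
    non-stop flag.
    """
    if indel < 0:
        d = -indel
        at = tract_cend if at is None else at
        edited = full_seq[: at - d] + full_seq[at:]
        new_end = tract_cend - d
    elif indel > 0:
        at = tract_cend if at is None else at
        edited = full_seq[:at] + (insert_base or full_seq[at - 1]) * indel + full_seq[at:]
        new_end = tract_cend + indel
    else:
        edited = full_seq
        new_end = tract_cend
    first_codon_start = 3 * ((new_end + 2) // 3) + 1  # 1-based, past the tract
    tail = edited[first_codon_start - 1 :]
    if len(tail) < 3:
        return "", False
    pep, stop = oracle_translate(tail)
    return pep, not stop


# --------------------------------------------------------------------------
# sequence construction helpers
# --------------------------------------------------------------------------

def _codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no stops)."""
    sense = sorted(set(_FORWARD))
    idx = rng.integers(0, len(sense), size=n)
    return "".join(sense[i] for i in idx)


def _bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def _scan_str(s: str, params: ScanParams) -> list[MicrosatelliteLocus]:
    return scan_sequence(GenomeSequence("tmp", s), params)


def _clean(rng: np.random.Generator, n: int, params: ScanParams) -> str:
    """Random sequence with no tract meeting the scan thresholds."""
    s = list(_bases(rng, n))
    for _ in range(200):
        loci = _scan_str("".join(s), params)
        if not loci:
            return "".join(s)
        for l in loci:
            mid = (l.start + l.end) // 2 - 1
            cur = s[mid]
            s[mid] = _BASES[(rng.integers(0, 3) + _BASES.index(cur) + 1) % 4]
    raise RuntimeError("could not clean background sequence")


@dataclass
class _Gene:
    index: int
    symbol: str
    transcript_id: str
    strand: str
    chrom: str = ""
    offset: int = 0                       # 0-based chromosome offset of block
    block: str = ""                       # plus-strand genomic block
    cds_intervals_block: list[tuple[int, int]] = field(default_factory=list)
    utr3_interval_block: tuple[int, int] | None = None
    coding_pos_block: list[int] = field(default_factory=list)  # 1-based, coding order
    utr_pos_block: list[int] = field(default_factory=list)
    tract: PlantedTract | None = None
    tract_coding_span: tuple[int, int] | None = None   # 1-based in CDS
    tract_block_span: tuple[int, int] | None = None    # 1-based genomic in block
    intron_tract: PlantedTract | None = None
    intron_tract_block_span: tuple[int, int] | None = None


def _build_gene(rng: np.random.Generator, gene: _Gene,
                params: ScanParams) -> None:
    """Assemble one gene block in place (CDS + introns + 3' UTR)."""
    tract = gene.tract
    for _ in range(500):
        pre_codons = int(rng.integers(7, 13))
        post_codons = int(rng.integers(9, 16))
        pre = "ATG" + _codons(rng, pre_codons)
        tract_seq = tract.motif * tract.unit_count if tract else ""
        filler = _bases(rng, (-len(tract_seq)) % 3)
        post = _codons(rng, post_codons) + "TAA"
        cds = pre + tract_seq + filler + post
        if tract:
            cstart = len(pre) + 1
            cend = len(pre) + len(tract_seq)
            nxt = (filler + post)[0]
            if pre[-1] == tract.motif[-1] or nxt == tract.motif[0]:
                continue  # guard bases must not extend the tract
        pep, stop = oracle_translate(cds)
        if not stop or "*" in pep:
            continue
        found = _scan_str(cds, params)
        expected = set()
        if tract:
            expected = {(cstart, cend, tract.motif, tract.unit_count)}
        if {(l.start, l.end, l.motif, l.unit_count) for l in found} != expected:
            continue
        break
    else:
        raise RuntimeError(f"could not assemble CDS for {gene.symbol}")

    # exon structure: tract (if any) stays within a single exon
    n_exons = int(rng.integers(2, 4)) if gene.intron_tract else int(rng.integers(1, 4))
    cuts: list[int] = []
    for _ in range(200):
        cuts = sorted(rng.choice(np.arange(12, len(cds) - 12), size=n_exons - 1,
                                 replace=False).tolist()) if n_exons > 1 else []
        if tract and any(cstart - 2 <= c <= cend + 1 for c in cuts):
            continue
        if all(b - a >= 10 for a, b in zip([0] + cuts, cuts + [len(cds)])):
            break
    else:
        raise RuntimeError(f"could not place exon boundaries for {gene.symbol}")
    bounds = [0] + cuts + [len(cds)]
    exons = [cds[a:b] for a, b in zip(bounds, bounds[1:])]

    introns = []
    for i in range(n_exons - 1):
        body = _clean(rng, int(rng.integers(30, 55)), params)
        if gene.intron_tract and i == 0:
            t = gene.intron_tract
            ts = t.motif * t.unit_count
            mid = len(body) // 2
            left, right = body[:mid], body[mid:]
            # guard the intron tract exactly like a CDS tract
            while left and left[-1] == t.motif[-1]:
                left = left[:-1]
            while right and right[0] == t.motif[0]:
                right = right[1:]
            body = left + ts + right
        introns.append(body)

    utr = _clean(rng, int(rng.integers(45, 76)), params)

    # transcript-oriented block with bookkeeping
    block_parts: list[str] = []
    cds_intervals: list[tuple[int, int]] = []
    coding_pos: list[int] = []
    pos = 0
    intron_tract_span = None
    for i, exon in enumerate(exons):
        cds_intervals.append((pos + 1, pos + len(exon)))
        coding_pos.extend(range(pos + 1, pos + len(exon) + 1))
        block_parts.append(exon)
        pos += len(exon)
        if i < len(introns):
            if gene.intron_tract and i == 0:
                t = gene.intron_tract
                ts = t.motif * t.unit_count
                j = introns[i].index(ts)
                intron_tract_span = (pos + j + 1, pos + j + t.tract_len)
            block_parts.append(introns[i])
            pos += len(introns[i])
    utr_interval = (pos + 1, pos + len(utr))
    utr_pos = list(range(pos + 1, pos + len(utr) + 1))
    block_parts.append(utr)
    pos += len(utr)
    block = "".join(block_parts)

    if tract:
        tract_block_span = (coding_pos[cstart - 1], coding_pos[cend - 1])
        gene.tract_coding_span = (cstart, cend)
    else:
        tract_block_span = None

    if gene.strand == "-":
        B = len(block)
        block = _revcomp(block)
        mirror = lambda iv: (B - iv[1] + 1, B - iv[0] + 1)
        cds_intervals = sorted(mirror(iv) for iv in cds_intervals)
        utr_interval = mirror(utr_interval)
        coding_pos = [B - p + 1 for p in coding_pos]
        utr_pos = [B - p + 1 for p in utr_pos]
        if tract_block_span:
            tract_block_span = mirror(tract_block_span)
        if intron_tract_span:
            intron_tract_span = mirror(intron_tract_span)

    gene.block = block
    gene.cds_intervals_block = cds_intervals
    gene.utr3_interval_block = utr_interval
    gene.coding_pos_block = coding_pos
    gene.utr_pos_block = utr_pos
    gene.tract_block_span = tract_block_span
    gene.intron_tract_block_span = intron_tract_span


# --------------------------------------------------------------------------
# chromosome assembly, verification and patching
# --------------------------------------------------------------------------

@dataclass
class _Chromosome:
    name: str
    seq: list[str]
    genes: list[_Gene]
    planted: list[dict]          # chrom-coordinate truth loci
    protected: set[int]          # 0-based positions inside planted tracts
    cds_info: dict[int, tuple[int, int]]  # 0-based pos -> (gene index, coding index)


def _plus_motif(motif: str, strand: str) -> str:
    return motif if strand == "+" else _revcomp(motif)


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _assemble_chromosome(rng: np.random.Generator, name: str,
                         genes: list[_Gene],
                         intergenic: list[PlantedTract],
                         params: ScanParams) -> _Chromosome:
    parts: list[str] = [_clean(rng, 60, params)]
    planted: list[dict] = []
    offset = len(parts[0])
    for gi, gene in enumerate(genes):
        gene.chrom = name
        gene.offset = offset
        parts.append(gene.block)
        offset += len(gene.block)
        gap = _clean(rng, int(rng.integers(40, 70)), params)
        if gi < len(intergenic):
            t = intergenic[gi]
            ts = t.motif * t.unit_count
            mid = len(gap) // 2
            left, right = gap[:mid], gap[mid:]
            while left and left[-1] == t.motif[-1]:
                left = left[:-1]
            while right and right[0] == t.motif[0]:
                right = right[1:]
            gap = left + ts + right
            start = offset + len(left) + 1
            planted.append({
                "start": start, "end": start + t.tract_len - 1,
                "motif": t.motif, "unit_count": t.unit_count,
                "placement": "intergenic", "gene": "", "transcript": "",
            })
        parts.append(gap)
        offset += len(gap)
    parts.append(_clean(rng, 60, params))
    seq = list("".join(parts))

    protected: set[int] = set()
    cds_info: dict[int, tuple[int, int]] = {}
    for gi, gene in enumerate(genes):
        for ci, bp in enumerate(gene.coding_pos_block):
            cds_info[gene.offset + bp - 1] = (gi, ci)
        if gene.tract_block_span:
            s, e = gene.tract_block_span
            start, end = gene.offset + s, gene.offset + e
            planted.append({
                "start": start, "end": end,
                "motif": _plus_motif(gene.tract.motif, gene.strand),
                "unit_count": gene.tract.unit_count,
                "placement": "CDS", "gene": gene.symbol,
                "transcript": gene.transcript_id,
            })
        if gene.intron_tract_block_span:
            s, e = gene.intron_tract_block_span
            planted.append({
                "start": gene.offset + s, "end": gene.offset + e,
                "motif": _plus_motif(gene.intron_tract.motif, gene.strand),
                "unit_count": gene.intron_tract.unit_count,
                "placement": "intron", "gene": gene.symbol,
                "transcript": gene.transcript_id,
            })
    for rec in planted:
        protected.update(range(rec["start"] - 1, rec["end"]))
    return _Chromosome(name, seq, genes, planted, protected, cds_info)


def _coding_base(chrom: _Chromosome, gene: _Gene, pos0: int) -> str:
    b = chrom.seq[pos0]
    return b if gene.strand == "+" else _COMP[b]


def _patch(chrom: _Chromosome, locus: MicrosatelliteLocus,
           rng: np.random.Generator) -> None:
    """Break an unplanted tract with one base change.

    Positions inside planted tracts are never touched; inside CDS the
    replacement keeps the wild-type codon a sense codon.
    """
    span = list(range(locus.start - 1, locus.end))
    mid = len(span) // 2
    order = sorted(span, key=lambda p: abs(p - span[mid]))
    for pos0 in order:
        if pos0 in chrom.protected:
            continue
        cur = chrom.seq[pos0]
        choices = [b for b in _BASES if b != cur]
        choices = [choices[i] for i in rng.permutation(len(choices))]
        info = chrom.cds_info.get(pos0)
        if info is None:
            chrom.seq[pos0] = choices[0]
            return
        gi, ci = info
        gene = chrom.genes[gi]
        codon_idx = ci // 3
        codon_pos0 = [gene.offset + gene.coding_pos_block[3 * codon_idx + k] - 1
                      for k in range(3)]
        for cand in choices:
            coding_cand = cand if gene.strand == "+" else _COMP[cand]
            codon = "".join(
                coding_cand if p == pos0 else _coding_base(chrom, gene, p)
                for p in codon_pos0
            )
            if codon not in _STOPS:
                chrom.seq[pos0] = cand
                return
    raise RuntimeError(f"could not patch accidental tract at {locus.key()}")


def _verify_and_patch(chrom: _Chromosome, params: ScanParams,
                      rng: np.random.Generator) -> None:
    expected = {
        (r["start"], r["end"], r["motif"], r["unit_count"])
        for r in chrom.planted
    }
    for _ in range(300):
        found = _scan_str("".join(chrom.seq), params)
        found_keys = {(l.start, l.end, l.motif, l.unit_count) for l in found}
        if expected - found_keys:
            raise RuntimeError(
                f"planted loci missing after assembly: {expected - found_keys}"
            )
        extra = [l for l in found
                 if (l.start, l.end, l.motif, l.unit_count) not in expected]
        if not extra:
            return
        for l in extra:
            _patch(chrom, l, rng)
    raise RuntimeError("chromosome failed to converge to planted loci")


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    fasta: Path
    gtf: Path
    truth_loci: Path
    truth_peptides: Path
    gene_symbols: list[str]


def make_genome(spec: FixtureSpec, outdir: str | Path,
                params: ScanParams | None = None) -> GenomeFixture:
    """Write genome.fasta, annotation.gtf and the two truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ScanParams()

    last_err: Exception | None = None
    for attempt in range(20):
        rng = np.random.default_rng((spec.seed, attempt))
        try:
            return _make_genome_once(spec, outdir, params, rng)
        except RuntimeError as err:  # resample the whole build
            last_err = err
            logger.warning("fixture build attempt %d failed (%s); retrying",
                           attempt, err)
    raise RuntimeError(f"fixture generation failed: {last_err}")


def _make_genome_once(spec: FixtureSpec, outdir: Path, params: ScanParams,
                      rng: np.random.Generator) -> GenomeFixture:
    cds_tracts = [t for t in spec.planted if t.placement == "CDS"]
    intron_tracts = [t for t in spec.planted if t.placement == "intron"]
    intergenic = [t for t in spec.planted if t.placement == "intergenic"]

    chroms: list[_Chromosome] = []
    gene_symbols: list[str] = []
    gidx = 0
    for ci in range(spec.n_chromosomes):
        genes: list[_Gene] = []
        for gj in range(spec.genes_per_chrom):
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gene = _Gene(
                index=gidx,
                symbol=f"GENE{gidx + 1}",
                transcript_id=f"TR{gidx + 1}",
                strand=strand,
            )
            if gidx < len(cds_tracts):
                gene.tract = cds_tracts[gidx]
            k = gidx - len(cds_tracts)
            if 0 <= k < len(intron_tracts):
                gene.intron_tract = intron_tracts[k]
            _build_gene(rng, gene, params)
            genes.append(gene)
            gene_symbols.append(gene.symbol)
            gidx += 1
        chrom = _assemble_chromosome(
            rng, f"chr{ci + 1}", genes,
            intergenic if ci == 0 else [], params,
        )
        _verify_and_patch(chrom, params, rng)
        chroms.append(chrom)
    if gidx < len(cds_tracts) + len(intron_tracts):
        raise ValueError("more planted genic tracts than genes")

    # truth peptides from the final, patched sequence
    peptide_rows: list[dict] = []
    for chrom in chroms:
        for gene in chrom.genes:
            if gene.tract is None:
                continue
            full = "".join(
                _coding_base(chrom, gene, gene.offset + bp - 1)
                for bp in gene.coding_pos_block + gene.utr_pos_block
            )
            cstart, cend = gene.tract_coding_span
            rec = next(r for r in chrom.planted
                       if r["placement"] == "CDS" and r["gene"] == gene.symbol)
            for del_len, frame_class in ((2, 1), (1, 2)):
                pep, non_stop = oracle_downstream(full, cstart, cend, -del_len)
                if not pep:
                    raise RuntimeError(
                        f"degenerate truth peptide for {gene.symbol}"
                    )
                peptide_rows.append({
                    "chrom": chrom.name, "start": rec["start"],
                    "end": rec["end"], "motif": rec["motif"],
                    "gene": gene.symbol, "transcript": gene.transcript_id,
                    "frame_class": frame_class, "del_len": del_len,
                    "peptide": pep, "non_stop": int(non_stop),
                })

    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom.name}\n")
            s = "".join(chrom.seq)
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")

    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for chrom in chroms:
            for gene in chrom.genes:
                attrs = (f'gene_id "{gene.symbol}"; '
                         f'transcript_id "{gene.transcript_id}"; '
                         f'gene_name "{gene.symbol}";')
                cum = 0
                ivs = gene.cds_intervals_block
                order = ivs if gene.strand == "+" else list(reversed(ivs))
                rows = []
                for s, e in order:
                    frame = (3 - cum % 3) % 3
                    rows.append((s, e, frame))
                    cum += e - s + 1
                for s, e, frame in sorted(rows):
                    fh.write(
                        f"{chrom.name}\tmsneoforge\tCDS\t{gene.offset + s}\t"
                        f"{gene.offset + e}\t.\t{gene.strand}\t{frame}\t{attrs}\n"
                    )
                us, ue = gene.utr3_interval_block
                fh.write(
                    f"{chrom.name}\tmsneoforge\tthree_prime_utr\t"
                    f"{gene.offset + us}\t{gene.offset + ue}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )

    truth_loci = outdir / "truth_loci.tsv"
    with open(truth_loci, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif\tunit_count\tplacement\tgene\t"
                 "transcript\n")
        for chrom in chroms:
            for r in sorted(chrom.planted, key=lambda r: r["start"]):
                fh.write(
                    f"{chrom.name}\t{r['start']}\t{r['end']}\t{r['motif']}\t"
                    f"{r['unit_count']}\t{r['placement']}\t{r['gene']}\t"
                    f"{r['transcript']}\n"
                )

    truth_peptides = outdir / "truth_peptides.tsv"
    with open(truth_peptides, "w") as fh:
        cols = ["chrom", "start", "end", "motif", "gene", "transcript",
                "frame_class", "del_len", "peptide", "non_stop"]
        fh.write("\t".join(cols) + "\n")
        for row in peptide_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    return GenomeFixture(
        fasta=fasta, gtf=gtf, truth_loci=truth_loci,
        truth_peptides=truth_peptides, gene_symbols=gene_symbols,
    )


def make_expression(spec: FixtureSpec, outdir: str | Path,
                    gene_symbols: list[str] | None = None
                    ) -> tuple[Path, Path, Path]:
    """Expression matrix + metadata + planted DE gene list.

    Null genes share one log-normal distribution across groups; DE genes
    are shifted multiplicatively in tumor samples by the design's effect
    size.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = spec.expression
    rng = np.random.default_rng((spec.seed, 7001))
    genes = list(gene_symbols or [])
    genes += [f"XGENE{i + 1}" for i in range(max(0, d.n_genes - len(genes)))]
    genes = genes[: max(d.n_genes, len(genes))]
    de_genes = genes[: d.n_de_genes]
    samples = ([f"N{i + 1:02d}" for i in range(d.n_normal)]
               + [f"T{i + 1:02d}" for i in range(d.n_tumor)])
    mu = rng.normal(np.log(100.0), 1.0, size=len(genes))
    mat = np.exp(mu[:, None] + rng.normal(0.0, d.sigma,
                                          size=(len(genes), len(samples))))
    mat[np.isin(genes, de_genes), d.n_normal:] *= d.effect_size

    matrix = outdir / "expression.tsv"
    with open(matrix, "w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for g, row in zip(genes, mat):
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    metadata = outdir / "samples.tsv"
    with open(metadata, "w") as fh:
        fh.write("sample\tcohort\tgroup\tmsi_status\n")
        for i, s in enumerate(samples):
            group = "normal" if i < d.n_normal else "tumor"
            msi = "MSS" if group == "normal" else "MSI-H"
            fh.write(f"{s}\t{d.cohort}\t{group}\t{msi}\n")
    truth = outdir / "truth_de_genes.txt"
    truth.write_text("".join(g + "\n" for g in de_genes))
    return matrix, metadata, truth


def make_evidence(spec: FixtureSpec, outdir: str | Path,
                  variant_keys: list[str],
                  epitopes: list[str]) -> tuple[Path, Path, Path]:
    """dbSNP-like, ClinVar-like and IEDB-like tables for a fraction of keys."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((spec.seed, 7002))
    frac = spec.evidence_fraction

    def pick(keys: list[str]) -> list[str]:
        keys = sorted(set(keys))
        n = int(round(frac * len(keys)))
        if n == 0:
            return []
        chosen = rng.choice(len(keys), size=n, replace=False)
        return [keys[i] for i in sorted(chosen)]

    dbsnp = outdir / "dbsnp_like.tsv"
    with open(dbsnp, "w") as fh:
        fh.write("variant_key\trsid\tpopulation_frequency\n")
        for i, k in enumerate(pick(variant_keys)):
            fh.write(f"{k}\trs{900000 + i}\t{rng.uniform(1e-4, 0.2):.5f}\n")
    clinvar = outdir / "clinvar_like.tsv"
    phenos = ["colorectal cancer", "Lynch syndrome", "endometrial cancer",
              "not provided"]
    with open(clinvar, "w") as fh:
        fh.write("variant_key\tphenotype\tclinical_significance\n")
        for k in pick(variant_keys):
            ph = phenos[int(rng.integers(0, len(phenos)))]
            fh.write(f"{k}\t{ph}\tuncertain_significance\n")
    iedb = outdir / "iedb_like.tsv"
    with open(iedb, "w") as fh:
        fh.write("peptide\tassay\tqualitative_measure\n")
        for k in pick(epitopes):
            fh.write(f"{k}\tELISPOT\tPositive\n")
    return dbsnp, clinvar, iedb
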