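"""Canonical frameshift variants and junction-excluded downstream peptides.

Indels whose sizes are congruent modulo 3 shift the reading frame
identically and therefore yield the same downstream protein.  Every
frameshifting indel in a microsatellite tract consequently falls into one
of two classes -- a 3n+1 shift or a 3n+2 shift -- and each class is
represented here by a single canonical in-silico deletion at the locus: a
two-base deletion (class 1, covering all 3n+1 indels) and a one-base
deletion (class 2, covering all 3n+2 indels).

The mutant downstream peptide is taken junction-excluded: translation of
the mutant transcript is reported from the first codon all three of whose
bases lie strictly 3' of the microsatellite tract in mutant coordinates,
avoiding the combinatorial complexity of junction-spanning sequence (which
depends on the exact indel size and placement).  Translation continues into
the annotated 3' UTR; peptides with no stop by transcript end are kept and
flagged ``non_stop``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam
from Bio.Seq import Seq

from .genome_io import (
    GenomeSequence,
    TranscriptModel,
    extract_cds,
    extract_utr3,
)
from .repeat_scan import MicrosatelliteLocus

logger = logging.getLogger("msneoforge")


@dataclass(frozen=True)
class FrameshiftVariant:
    """One canonical deletion at a coding microsatellite on a transcript.

    ``frame_class`` is the shift of the reading frame modulo 3:
    ``(-del_len) % 3`` -- a 2-base deletion gives class 1 (all 3n+1
    indels), a 1-base deletion gives class 2 (all 3n+2 indels).
    ``cds_tract_start/end`` locate the tract's in-CDS portion in 1-based
    coding coordinates; the VCF fields are left-aligned with an anchor
    base, per indel normalization rules.
    """

    locus: MicrosatelliteLocus
    transcript_id: str
    gene_symbol: str
    del_len: int
    cds_tract_start: int
    cds_tract_end: int
    chrom: str
    vcf_pos: int
    vcf_ref: str
    vcf_alt: str

    @property
    def frame_class(self) -> int:
        return (-self.del_len) % 3

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.vcf_pos}:{self.vcf_ref}:{self.vcf_alt}"


@dataclass
class FrameshiftPeptide:
    """A deduplicated junction-excluded downstream frameshift peptide.

    ``sources`` lists contributing (gene_symbol, transcript_id, locus key,
    frame_class) tuples; ``junction_excluded_from`` is the 1-based index of
    the first mutant codon used.
    """

    peptide: str
    sources: list[tuple[str, str, str, int]]
    non_stop: bool = False
    junction_excluded_from: int = 1
    full_tail: str = ""  # junction-included mutant tail, for reference

    @property
    def gene_symbols(self) -> list[str]:
        return sorted({s[0] for s in self.sources})

    @property
    def peptide_id(self) -> str:
        return peptide_id(self.peptide)


def peptide_id(peptide: str) -> str:
    """Stable identifier derived from the peptide string itself."""
    return "FSP_" + hashlib.sha1(peptide.encode()).hexdigest()[:12].upper()


def translate(nt: str) -> tuple[str, bool]:
    """Translate from position 1 with the standard genetic code.

    Halts at the first stop codon; trailing 1-2 bases are ignored.
    Returns ``(peptide, stop_found)``.  N in the sequence is an error (the
    caller flags the transcript as untranslatable).
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    if "N" in nt:
        raise ValueError("sequence contains N; untranslatable")
    trimmed = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(trimmed).translate())
    stop_at = aa.find("*")
    if stop_at == -1:
        return aa, False
    return aa[:stop_at], True


def coding_order_positions(transcript: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in coding (5'->3') order."""
    pos = [p for s, e in transcript.cds_intervals for p in range(s, e + 1)]
    if transcript.strand == "-":
        pos.reverse()
    return pos


def tract_coding_span(locus: MicrosatelliteLocus,
                      transcript: TranscriptModel) -> tuple[int, int] | None:
    """1-based coding span of the locus' in-CDS portion, or None.

    Splicing makes the in-CDS bases of a tract contiguous in coding
    coordinates even when the tract crosses an intron.
    """
    order = coding_order_positions(transcript)
    idx = [i + 1 for i, p in enumerate(order) if locus.start <= p <= locus.end]
    if not idx:
        return None
    lo, hi = min(idx), max(idx)
    if hi - lo + 1 != len(idx):  # cannot happen with sorted CDS intervals
        raise ValueError("tract maps to non-contiguous coding positions")
    return lo, hi


def left_align_deletion(chrom_seq: GenomeSequence, start: int,
                        del_len: int) -> tuple[int, str, str]:
    """Left-align a deletion of ``del_len`` bases beginning at ``start``.

    Standard VCF normalization: shift the deleted window left while the
    base preceding it equals its last base, then anchor on the preceding
    base.  Returns (pos, ref, alt).
    """
    p = start
    s = chrom_seq.residues
    while p > 2 and s[p - 2] == s[p + del_len - 2]:
        p -= 1
    if p < 2:
        raise ValueError("deletion reaches the chromosome start; cannot anchor")
    ref = s[p - 2 : p + del_len - 1]
    return p - 1, ref, ref[0]


def canonical_variants(
    locus: MicrosatelliteLocus,
    transcript: TranscriptModel,
    genome: Mapping[str, GenomeSequence],
) -> list[FrameshiftVariant]:
    """The two canonical deletions (2 bp -> class 1, 1 bp -> class 2).

    The in-CDS portion of the tract must be at least 3 bases so that two
    bases can be deleted while at least one tract base remains; shorter
    overlaps are skipped with a warning.  VCF fields are left-aligned
    against the genome independently of where the deletion is placed for
    peptide generation (placement within the tract is irrelevant to the
    downstream product).
    """
    span = tract_coding_span(locus, transcript)
    if span is None:
        return []
    lo, hi = span
    if hi - lo + 1 < 3:
        logger.warning(
            "tract %s has <3 bases within CDS of %s; skipped",
            locus.key(), transcript.transcript_id,
        )
        return []
    chrom_seq = genome[locus.chrom]
    out = []
    for del_len in (2, 1):
        pos, ref, alt = left_align_deletion(chrom_seq, locus.start, del_len)
        out.append(
            FrameshiftVariant(
                locus=locus,
                transcript_id=transcript.transcript_id,
                gene_symbol=transcript.gene_symbol,
                del_len=del_len,
                cds_tract_start=lo,
                cds_tract_end=hi,
                chrom=locus.chrom,
                vcf_pos=pos,
                vcf_ref=ref,
                vcf_alt=alt,
            )
        )
    return out


def apply_variant(transcript_seq: str, variant: FrameshiftVariant) -> str:
    """Delete the variant's bases from a coding-orientation sequence.

    The canonical deletion removes the last ``del_len`` bases of the
    tract's in-CDS portion; result length = input length - del_len.
    """
    hi = variant.cds_tract_end
    d = variant.del_len
    if hi > len(transcript_seq) or hi - d + 1 < 1:
        raise ValueError("variant coordinates do not map inside the sequence")
    return transcript_seq[: hi - d] + transcript_seq[hi:]


def first_post_tract_codon(mutant_tract_end: int) -> int:
    """1-based start of the first codon entirely 3' of the mutant tract."""
    n_codons_covered = -(-mutant_tract_end // 3)  # ceil
    return 3 * n_codons_covered + 1


def downstream_peptide(
    transcript: TranscriptModel,
    variant: FrameshiftVariant,
    genome: Mapping[str, GenomeSequence],
) -> FrameshiftPeptide | None:
    """Junction-excluded downstream peptide for one canonical variant.

    Builds CDS + 3' UTR in coding orientation, applies the deletion,
    translates the standard codon grid of the mutant sequence and reports
    the tail from the first codon fully past the tract.  Returns None when
    the frameshifted tail stops before that codon, when no full post-tract
    codon exists, or when the sequence is untranslatable (N).
    """
    full = extract_cds(genome, transcript) + extract_utr3(genome, transcript)
    if "N" in full:
        logger.warning("transcript %s untranslatable (contains N)",
                       transcript.transcript_id)
        return None
    mutant = apply_variant(full, variant)
    tract_end_mut = variant.cds_tract_end - variant.del_len
    p = first_post_tract_codon(tract_end_mut)
    if p + 2 > len(mutant):
        return None
    tail_nt = mutant[p - 1 :]
    peptide, stop_found = translate(tail_nt)
    if not peptide:
        return None  # frameshift runs straight into a stop
    # junction-included tail, from the first codon touching the tract edge
    junc_start = 3 * ((tract_end_mut - 1) // 3) if tract_end_mut >= 1 else 0
    full_tail, _ = translate(mutant[junc_start:]) if len(mutant) - junc_start >= 3 else ("", False)
    return FrameshiftPeptide(
        peptide=peptide,
        sources=[(
            variant.gene_symbol,
            variant.transcript_id,
            variant.locus.key(),
            variant.frame_class,
        )],
        non_stop=not stop_found,
        junction_excluded_from=(p - 1) // 3 + 1,
        full_tail=full_tail,
    )


def deduplicate(peptides: Sequence[FrameshiftPeptide]) -> list[FrameshiftPeptide]:
    """One record per distinct peptide string, sources merged and sorted."""
    by_seq: dict[str, FrameshiftPeptide] = {}
    for p in peptides:
        if p.peptide in by_seq:
            rec = by_seq[p.peptide]
            rec.sources = sorted(set(rec.sources) | set(p.sources))
            rec.non_stop = rec.non_stop or p.non_stop
        else:
            by_seq[p.peptide] = FrameshiftPeptide(
                peptide=p.peptide,
                sources=sorted(set(p.sources)),
                non_stop=p.non_stop,
                junction_excluded_from=p.junction_excluded_from,
                full_tail=p.full_tail,
            )
    return [by_seq[k] for k in sorted(by_seq)]


def generate_peptides(
    pairs: Sequence[tuple[MicrosatelliteLocus, TranscriptModel]],
    genome: Mapping[str, GenomeSequence],
) -> tuple[list[FrameshiftVariant], list[FrameshiftPeptide]]:
    """Variants and deduplicated peptides for all coding (locus, transcript) pairs."""
    variants: list[FrameshiftVariant] = []
    raw: list[FrameshiftPeptide] = []
    for locus, transcript in pairs:
        if not transcript.frame_ok:
            logger.warning("transcript %s out of frame; skipped",
                           transcript.transcript_id)
            continue
        for variant in canonical_variants(locus, transcript, genome):
            variants.append(variant)
            pep = downstream_peptide(transcript, variant, genome)
            if pep is not None:
                raw.append(pep)
    return variants, deduplicate(raw)


def write_vcf(variants: Sequence[FrameshiftVariant],
              genome: Mapping[str, GenomeSequence],
              path: str | Path) -> None:
    """Emit unique canonical deletions as a VCF 4.2 file (sorted, anchored)."""
    header = pysam.VariantHeader()
    for chrom in sorted(genome):
        header.contigs.add(chrom, length=genome[chrom].length)
    header.info.add("GENE", ".", "String", "Gene symbols at this locus")
    header.info.add("TRANSCRIPT", ".", "String", "Transcripts at this locus")
    header.info.add("MOTIF", 1, "String", "Microsatellite motif")
    header.info.add("UNITS", 1, "Integer", "Microsatellite unit count")
    header.info.add("FRAME_CLASS", 1, "Integer",
                    "Reading-frame shift class (1 = 3n+1, 2 = 3n+2)")
    merged: dict[tuple, dict] = {}
    for v in variants:
        key = (v.chrom, v.vcf_pos, v.vcf_ref, v.vcf_alt)
        rec = merged.setdefault(
            key,
            {"genes": set(), "transcripts": set(),
             "motif": v.locus.motif, "units": v.locus.unit_count,
             "frame_class": v.frame_class},
        )
        rec["genes"].add(v.gene_symbol)
        rec["transcripts"].add(v.transcript_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for key in sorted(merged):
            chrom, pos, ref, alt = key
            info = merged[key]
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            rec.info["GENE"] = ",".join(sorted(info["genes"]))
            rec.info["TRANSCRIPT"] = ",".join(sorted(info["transcripts"]))
            rec.info["MOTIF"] = info["motif"]
            rec.info["UNITS"] = info["units"]
            rec.info["FRAME_CLASS"] = info["frame_class"]
            vcf.write(rec)


def write_peptides_fasta(peptides: Sequence[FrameshiftPeptide],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.peptide_id}\n{p.peptide}\n")


def peptides_to_tsv(peptides: Sequence[FrameshiftPeptide],
                    path: str | Path) -> None:
    """Peptide id -> sources mapping (gene, transcript, locus, frame_class)."""
    with open(path, "w") as fh:
        fh.write("peptide_id\tpeptide\tgene\ttranscript\tlocus\t"
                 "frame_class\tnon_stop\tjunction_excluded_from\tfull_tail\n")
        for p in peptides:
            for gene, tid, locus, fc in p.sources:
                fh.write(
                    f"{p.peptide_id}\t{p.peptide}\t{gene}\t{tid}\t{locus}\t"
                    f"{fc}\t{int(p.non_stop)}\t{p.junction_excluded_from}\t"
                    f"{p.full_tail}\n"
                )
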