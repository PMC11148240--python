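"""Genome and gene-model input.

Reads multi-record FASTA genomes and GTF/GFF3 gene models, and assembles
strand-aware coding sequences per transcript.  Coordinates are 1-based,
fully closed throughout (the GFF convention); BED export elsewhere in the
package converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("msneoforge")

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Return residues for the 1-based closed interval [start, end]."""
        if start < 1 or end > self.length or start > end:
            raise ValueError(
                f"interval {start}-{end} out of bounds for {self.id} "
                f"(length {self.length})"
            )
        return self.residues[start - 1 : end]


@dataclass
class TranscriptModel:
    """A protein-coding transcript: ordered CDS intervals plus optional 3' UTR.

    ``cds_intervals`` are 1-based closed genomic intervals sorted by start,
    pairwise non-overlapping.  ``frame_ok`` is False when the summed CDS
    length is not divisible by 3 (the model is kept but flagged).
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        self.cds_intervals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping CDS intervals in {self.transcript_id}"
                )
        self.utr3_intervals = sorted(self.utr3_intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def frame_ok(self) -> bool:
        return self.cds_length % 3 == 0


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Residues are uppercased; characters outside {A, C, G, T, N} and
    duplicate record identifiers are hard errors, as is an empty file.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


def genome_index(sequences: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    """Index a sequence collection by id."""
    out: dict[str, GenomeSequence] = {}
    for s in sequences:
        if s.id in out:
            raise ValueError(f"duplicate sequence identifier {s.id!r}")
        out[s.id] = s
    return out


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def read_annotation(path: str | Path, dialect: str = "gtf") -> list[TranscriptModel]:
    """Read CDS (and three_prime_utr) features from a GTF or GFF3 file.

    CDS features are grouped per transcript and sorted by genomic start.
    Transcripts whose total CDS length is not divisible by 3 are kept; the
    ``frame_ok`` property flags them.  CDS features without a transcript
    identifier, or with an unknown strand, are skipped with a warning.
    """
    if dialect not in {"gtf", "gff3"}:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    cds: dict[str, dict] = {}
    for ftype, target in (("CDS", "cds"), ("three_prime_utr", "utr3")):
        for feat in db.features_of_type(ftype):
            if dialect == "gtf":
                tid = _attr(feat, "transcript_id")
            else:
                tid = _attr(feat, "Parent", "transcript_id")
            if tid is None:
                logger.warning(
                    "%s feature at %s:%d-%d lacks a transcript id; skipped",
                    ftype, feat.seqid, feat.start, feat.end,
                )
                continue
            if ftype == "CDS" and feat.strand not in {"+", "-"}:
                logger.warning(
                    "CDS of %s has unknown strand %r; skipped", tid, feat.strand
                )
                continue
            entry = cds.setdefault(
                tid,
                {
                    "gene_id": _attr(feat, "gene_id", "gene") or tid,
                    "gene_symbol": _attr(feat, "gene_name", "Name", "gene_id")
                    or tid,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "cds": [],
                    "utr3": [],
                },
            )
            entry[target].append((feat.start, feat.end))

    models: list[TranscriptModel] = []
    for tid, entry in cds.items():
        if not entry["cds"]:
            continue
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            gene_symbol=entry["gene_symbol"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            cds_intervals=entry["cds"],
            utr3_intervals=entry["utr3"],
        )
        if not model.frame_ok:
            logger.warning(
                "transcript %s CDS length %d not divisible by 3; flagged",
                tid, model.cds_length,
            )
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.cds_intervals[0][0], m.transcript_id))
    return models


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _concat(genome: Mapping[str, GenomeSequence], chrom: str,
            intervals: list[tuple[int, int]]) -> str:
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} absent from genome")
    ref = genome[chrom]
    return "".join(ref.slice(s, e) for s, e in intervals)


def extract_cds(genome: Mapping[str, GenomeSequence],
                transcript: TranscriptModel) -> str:
    """Spliced coding sequence in coding (5'->3') orientation.

    Minus-strand transcripts are reverse-complemented after concatenating
    the genomic intervals in ascending order.  Out-of-bounds intervals are
    hard errors; a returned sequence may contain N (callers flag and skip
    translation for such transcripts).
    """
    seq = _concat(genome, transcript.chrom, transcript.cds_intervals)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    if "N" in seq:
        logger.warning("CDS of %s contains N; flagged as untranslatable",
                       transcript.transcript_id)
    return seq


def extract_utr3(genome: Mapping[str, GenomeSequence],
                 transcript: TranscriptModel) -> str:
    """Spliced 3' UTR sequence in coding orientation ('' when unannotated)."""
    if not transcript.utr3_intervals:
        return ""
    seq = _concat(genome, transcript.chrom, transcript.utr3_intervals)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq
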