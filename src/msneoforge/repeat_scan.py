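"""Microsatellite (short tandem repeat) detection.

A microsatellite is a maximal tract of a tandemly repeated primitive motif
of 1-5 bp.  Defaults follow the thresholds used to build the catalogue:
homopolymer runs must exceed five units (>= 6), motifs of 2-5 bp need at
least three whole units.  Scanning is performed on the plus strand; tract
spans are strand-symmetric.

Tract definition (deterministic and oracle-checkable):
* only whole units are counted -- a trailing partial unit is excluded from
  the span;
* the motif is primitive (an ``AAAA...`` run is reported once with motif
  ``A``, never as motif ``AA``);
* a tract is anchored at its leftmost attainable start, and after a tract
  is emitted, scanning for that motif length resumes at the first base
  after it, so tracts of one motif length never overlap;
* tracts containing N are never produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome_io import GenomeSequence, TranscriptModel

logger = logging.getLogger("msneoforge")

#: minimum whole-unit counts per motif length: homopolymers must exceed
#: five units; 2-5 bp motifs need at least three repetitions.
DEFAULT_MIN_UNITS = {1: 6, 2: 3, 3: 3, 4: 3, 5: 3}

MOTIF_LENGTHS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ScanParams:
    """Unit-count thresholds per motif length (1-5 bp motifs only)."""

    min_units_by_motif_len: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_UNITS)
    )

    def __post_init__(self) -> None:
        if set(self.min_units_by_motif_len) != set(MOTIF_LENGTHS):
            raise ValueError("motif lengths must be exactly {1,2,3,4,5}")
        if any(v < 2 for v in self.min_units_by_motif_len.values()):
            raise ValueError("all minimum unit counts must be >= 2")


@dataclass(frozen=True, order=True)
class MicrosatelliteLocus:
    """A maximal primitive-motif repeat tract (1-based closed genomic span)."""

    chrom: str
    start: int
    end: int
    motif: str
    unit_count: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.unit_count:
            raise ValueError("span length must equal motif_len * unit_count")

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def tract_len(self) -> int:
        return self.end - self.start + 1

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter word."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def scan_sequence(seq: GenomeSequence,
                  params: ScanParams | None = None) -> list[MicrosatelliteLocus]:
    """Find all maximal microsatellite tracts in one sequence.

    Runs one pass per motif length over a precomputed period-``k`` match
    profile (``s[j] == s[j+k]``), emitting leftmost-anchored whole-unit
    tracts and resuming after each.  Output is sorted by start, then motif
    length.
    """
    params = params or ScanParams()
    s = seq.residues
    n = len(s)
    loci: list[MicrosatelliteLocus] = []
    for k in MOTIF_LENGTHS:
        min_units = params.min_units_by_motif_len[k]
        if n < k * min_units:
            continue
        # run[j] = number of consecutive positions j' >= j with s[j']==s[j'+k],
        # N never matching; computed right-to-left.
        run = [0] * (n + 1)
        for j in range(n - k - 1, -1, -1):
            if s[j] == s[j + k] and s[j] != "N":
                run[j] = run[j + 1] + 1
        i = 0
        while i + k <= n:
            units = 1 + run[i] // k
            if units >= min_units:
                motif = s[i : i + k]
                if "N" not in motif and is_primitive(motif):
                    end = i + units * k  # exclusive, whole units only
                    loci.append(
                        MicrosatelliteLocus(
                            chrom=seq.id,
                            start=i + 1,
                            end=end,
                            motif=motif,
                            unit_count=units,
                        )
                    )
                    i = end
                    continue
            i += 1
    loci.sort(key=lambda l: (l.start, l.motif_len))
    return loci


def scan_genome(sequences: Iterable[GenomeSequence],
                params: ScanParams | None = None) -> list[MicrosatelliteLocus]:
    out: list[MicrosatelliteLocus] = []
    for seq in sequences:
        out.extend(scan_sequence(seq, params))
    return out


def intersect_coding(
    loci: Sequence[MicrosatelliteLocus],
    transcripts: Sequence[TranscriptModel],
) -> list[tuple[MicrosatelliteLocus, TranscriptModel]]:
    """Pairs of (locus, transcript) sharing >= 1 base with a CDS interval.

    A locus overlapping the CDS of k transcripts yields k pairs; loci with
    no overlap are dropped, and loci on chromosomes absent from the
    annotation are dropped with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.cds_intervals:
            tree.addi(s, e + 1, t)  # half-open for intervaltree
    pairs: list[tuple[MicrosatelliteLocus, TranscriptModel]] = []
    warned: set[str] = set()
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            if locus.chrom not in warned:
                logger.warning(
                    "chromosome %s absent from annotation; loci dropped",
                    locus.chrom,
                )
                warned.add(locus.chrom)
            continue
        hits = {iv.data.transcript_id: iv.data
                for iv in tree.overlap(locus.start, locus.end + 1)}
        for tid in sorted(hits):
            pairs.append((locus, hits[tid]))
    return pairs


def loci_to_tsv(loci: Sequence[MicrosatelliteLocus], path: str | Path) -> None:
    """Write loci as TSV (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif\tunit_count\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.motif}\t{l.unit_count}\n")


def loci_to_bed(loci: Sequence[MicrosatelliteLocus], path: str | Path) -> None:
    """Write loci as BED (0-based half-open), name = motif xN."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.motif}x{l.unit_count}\n")
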