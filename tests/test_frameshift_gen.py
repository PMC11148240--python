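"""Canonical variants, translation and the frame-class equivalence claim.

The central scientific claim: indels of sizes congruent modulo 3 placed
anywhere inside a microsatellite tract produce the same junction-excluded
downstream peptide, so two canonical deletions (2 bp and 1 bp) represent
all 3n+1 and 3n+2 frameshifts at a locus.  The oracle here performs the
literal string edit and an independent codon-table translation.
"""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from msneoforge.frameshift_gen import (
    FrameshiftPeptide,
    apply_variant,
    canonical_variants,
    deduplicate,
    downstream_peptide,
    left_align_deletion,
    translate,
)
from msneoforge.genome_io import GenomeSequence, TranscriptModel, genome_index
from msneoforge.repeat_scan import MicrosatelliteLocus, scan_sequence

from conftest import random_dna

STOPS = {"TAA", "TAG", "TGA"}


# --------------------------------------------------------------------------
# independent oracle: literal edit + biopython translation of the tail
# --------------------------------------------------------------------------

def oracle_edit_downstream(full: str, cstart: int, cend: int,
                           kind: str, size: int, at: int,
                           insert: str = "") -> str | None:
    """Apply an arbitrary in-tract indel and translate past the tract.

    ``at`` is a 1-based coding position: for deletions the first deleted
    base (the deletion lies wholly inside [cstart, cend]); for insertions
    the base after which ``insert`` is placed.
    """
    if kind == "del":
        assert cstart <= at and at + size - 1 <= cend
        edited = full[: at - 1] + full[at - 1 + size :]
        new_end = cend - size
    elif kind == "ins":
        assert cstart - 1 <= at <= cend and len(insert) == size
        edited = full[:at] + insert + full[at:]
        new_end = cend + size
    else:  # wild type
        edited, new_end = full, cend
    p = 3 * math.ceil(new_end / 3) + 1
    tail = edited[p - 1 :]
    tail = tail[: len(tail) - len(tail) % 3]
    if len(tail) < 3:
        return None
    aa = str(Seq(tail).translate())
    pep = aa.split("*")[0]
    return pep or None


def make_single_exon_case(rng, motif: str, units: int, strand: str = "+"):
    """A one-exon gene carrying one tract; returns (genome, transcript, locus)."""
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in STOPS]
    while True:
        pre = "ATG" + "".join(sense[i] for i in rng.integers(0, 61, size=8))
        tract = motif * units
        filler = random_dna(rng, (-len(tract)) % 3)
        post = "".join(sense[i] for i in rng.integers(0, 61, size=12)) + "TAA"
        cds = pre + tract + filler + post
        if pre[-1] == motif[-1] or (filler + post)[0] == motif[0]:
            continue
        if "*" in str(Seq(cds).translate())[:-1]:
            continue
        utr = random_dna(rng, 60)
        chrom_fwd = random_dna(rng, 10) + cds + utr + random_dna(rng, 10)
        if strand == "+":
            chrom = chrom_fwd
            cds_iv = (11, 10 + len(cds))
            utr_iv = (11 + len(cds), 10 + len(cds) + len(utr))
        else:
            chrom = str(Seq(chrom_fwd).reverse_complement())
            n = len(chrom)
            cds_iv = (n - (10 + len(cds)) + 1, n - 11 + 1)
            utr_iv = (n - (10 + len(cds) + len(utr)) + 1, n - (11 + len(cds)) + 1)
        genome = genome_index([GenomeSequence("chr1", chrom)])
        transcript = TranscriptModel("t1", "g1", "G1", "chr1", strand,
                                     [cds_iv], [utr_iv])
        loci = [l for l in scan_sequence(genome["chr1"])
                if l.unit_count == units]
        if len(loci) != 1:
            continue  # accidental repeat elsewhere; resample
        full = cds + utr
        cstart, cend = len(pre) + 1, len(pre) + len(tract)
        # both canonical frameshifts must yield a non-degenerate peptide
        if any(oracle_edit_downstream(full, cstart, cend, "del", d,
                                      cend - d + 1) is None for d in (1, 2)):
            continue
        return genome, transcript, loci[0], full, (cstart, cend)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,expected",
        [("ATGTGA", ("M", True)),
         ("ATGAAAAAAACC", ("MKKT", False)),
         ("ATGAA", ("M", False)),
         ("ATGTAAATG", ("M", True))],
    )
    def test_examples(self, nt, expected):
        assert translate(nt) == expected

    def test_n_untranslatable(self):
        with pytest.raises(ValueError, match="N"):
            translate("ATGNAA")

    def test_too_short(self):
        with pytest.raises(ValueError):
            translate("AT")


class TestCanonicalVariants:
    def test_two_variants_with_expected_frame_classes(self):
        rng = np.random.default_rng(0)
        genome, transcript, locus, _, _ = make_single_exon_case(rng, "A", 7)
        variants = canonical_variants(locus, transcript, genome)
        assert sorted((v.del_len, v.frame_class) for v in variants) == [
            (1, 2), (2, 1)]

    def test_vcf_fields_left_aligned_and_anchored(self):
        # deletion in a homopolymer normalizes to the run start
        genome = genome_index([GenomeSequence("chr1", "TGCAAAAAAGT")])
        pos, ref, alt = left_align_deletion(genome["chr1"], start=8, del_len=2)
        # the A-run spans 4-9; the anchor is the C at position 3
        assert (pos, ref, alt) == (3, "CAA", "C")
        assert ref.startswith(alt)

    def test_left_alignment_shifts_through_rotated_repeat(self):
        # deleting "CA" inside ...TACACAC... shifts to the leftmost placement
        genome = genome_index([GenomeSequence("chr1", "GGTACACACTT")])
        pos, ref, alt = left_align_deletion(genome["chr1"], start=6, del_len=2)
        ref_check = genome["chr1"].residues[pos - 1 : pos - 1 + len(ref)]
        assert ref == ref_check and len(ref) == 3 and alt == ref[0]
        assert pos == 3  # anchored on the T before the AC run

    def test_short_cds_overlap_skipped(self, caplog):
        # only 2 tract bases inside the CDS: cannot delete 2 and keep one
        genome = genome_index([GenomeSequence("chr1", "TTATGAAAAAAGGCC")])
        locus = MicrosatelliteLocus("chr1", 6, 11, "A", 6)
        t = TranscriptModel("t", "g", "G", "chr1", "+", [(3, 7)])
        with caplog.at_level("WARNING", logger="msneoforge"):
            assert canonical_variants(locus, t, genome) == []

    def test_apply_variant_length(self):
        rng = np.random.default_rng(1)
        genome, transcript, locus, full, _ = make_single_exon_case(rng, "AC", 4)
        for v in canonical_variants(locus, transcript, genome):
            assert len(apply_variant(full, v)) == len(full) - v.del_len


class TestFrameClassEquivalence:
    @pytest.mark.parametrize("motif,units,strand", [
        ("A", 7, "+"), ("A", 8, "-"), ("AC", 4, "+"), ("AC", 5, "-"),
        ("AGC", 3, "+"), ("AAAG", 3, "-"), ("AAGGC", 3, "+"),
    ])
    def test_any_indel_matches_its_canonical_class(self, motif, units, strand):
        rng = np.random.default_rng(hash((motif, units, strand)) % 2**31)
        genome, transcript, locus, full, (cs, ce) = make_single_exon_case(
            rng, motif, units, strand)
        canon = {}
        for v in canonical_variants(locus, transcript, genome):
            pep = downstream_peptide(transcript, v, genome)
            assert pep is not None
            canon[v.frame_class] = pep.peptide
        wild = oracle_edit_downstream(full, cs, ce, "wt", 0, cs)
        tract_len = ce - cs + 1
        for s in range(1, 8):
            cls = (-s) % 3
            # deletions of size s at every admissible in-tract start
            for at in range(cs, ce - s + 2):
                got = oracle_edit_downstream(full, cs, ce, "del", s, at)
                expect = wild if cls == 0 else canon[cls]
                assert got == expect, (s, at, "del")
            # insertions of size s after every in-tract position
            cls_ins = s % 3
            for at in range(cs - 1, ce + 1):
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=s))
                got = oracle_edit_downstream(full, cs, ce, "ins", s, at,
                                             insert=ins)
                expect = wild if cls_ins == 0 else canon[cls_ins]
                assert got == expect, (s, at, "ins")
        assert tract_len >= 3

    def test_in_frame_deletion_neutral(self):
        rng = np.random.default_rng(5)
        _, _, _, full, (cs, ce) = make_single_exon_case(rng, "AGC", 4)
        wild = oracle_edit_downstream(full, cs, ce, "wt", 0, cs)
        got = oracle_edit_downstream(full, cs, ce, "del", 3, cs)
        assert got == wild


class TestDownstreamPeptide:
    def test_matches_oracle_on_canonical_deletions(self):
        rng = np.random.default_rng(2)
        for motif, units in [("A", 7), ("AC", 4), ("AGC", 3)]:
            genome, transcript, locus, full, (cs, ce) = make_single_exon_case(
                rng, motif, units)
            for v in canonical_variants(locus, transcript, genome):
                pep = downstream_peptide(transcript, v, genome)
                want = oracle_edit_downstream(
                    full, cs, ce, "del", v.del_len, ce - v.del_len + 1)
                assert pep is not None and pep.peptide == want

    def test_no_stop_symbol_in_peptides(self, small_run):
        result, _ = small_run
        assert all("*" not in p.peptide for p in result.peptides)

    def test_immediate_stop_returns_none(self):
        # frameshifted tail opens on a stop codon at the first post-tract codon
        chrom = "ATGAAAAAAATAACCTTGGTAG"
        #        M  K  K  (A7 tract at 4..10) ...
        genome = genome_index([GenomeSequence("chr1", chrom)])
        t = TranscriptModel("t", "g", "G", "chr1", "+", [(1, len(chrom))])
        locus = MicrosatelliteLocus("chr1", 4, 10, "A", 7)
        variants = canonical_variants(locus, t, genome)
        del1 = next(v for v in variants if v.del_len == 1)
        # mutant: ATG AAA AAA TAA ... -> first post-tract codon is TAA
        assert downstream_peptide(t, del1, genome) is None


class TestDeduplicate:
    def mk(self, pep, source):
        return FrameshiftPeptide(peptide=pep, sources=[source])

    def test_merges_sources(self):
        a = self.mk("MKL", ("G1", "t1", "chr1:1-6:A", 1))
        b = self.mk("MKL", ("G2", "t2", "chr1:9-14:A", 1))
        out = deduplicate([a, b])
        assert len(out) == 1 and len(out[0].sources) == 2
        assert out[0].gene_symbols == ["G1", "G2"]

    def test_idempotent_and_sorted(self):
        peps = [self.mk(p, ("G", "t", "l", 1)) for p in ["ZZ", "AA", "MM", "AA"]]
        once = deduplicate(peps)
        twice = deduplicate(once)
        assert [p.peptide for p in once] == ["AA", "MM", "ZZ"]
        assert [(p.peptide, p.sources) for p in once] == [
            (p.peptide, p.sources) for p in twice]

    def test_count_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        peps = [self.mk("".join("ACDEFG"[i] for i in rng.integers(0, 6, 5)),
                        ("G", "t", "l", 1)) for _ in range(200)]
        assert len(deduplicate(peps)) == len({p.peptide for p in peps})
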