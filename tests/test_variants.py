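"""Consequence annotation and the rare-missense filter."""

import dataclasses

import pytest
from Bio.Seq import Seq, reverse_complement

from varodds import (
    ReferenceMismatchError,
    Transcript,
    VariantCall,
    annotate_consequence,
    filter_rare_missense,
)


def make_transcript(cds="ATGCGTCTGTAA", strand="+"):
    """Single-exon transcript: genomic 11..(10+len) on chrX."""
    n = len(cds)
    if strand == "+":
        segs = ((11, 10 + n),)
        seq = cds
    else:
        segs = ((11, 10 + n),)
        seq = cds
    return Transcript(
        id="T1", chrom="chrX", strand=strand, cds_segments=segs, cds_sequence=seq,
        tx_start=1, tx_end=20 + n,
    )


class TestTranscriptValidation:
    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            Transcript("T", "c", "+", ((1, 4),), "ATGC")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="terminal stop"):
            Transcript("T", "c", "+", ((1, 9),), "ATGTAATAA")

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Transcript("T", "c", "+", ((1, 6), (4, 9)), "ATGCGTCTGTAA")

    def test_protein_derived_from_cds(self):
        t = make_transcript("ATGCGTCTGTAA")
        assert t.protein_sequence == "MRL"

    def test_mismatched_protein_rejected(self):
        with pytest.raises(ValueError, match="protein_sequence"):
            Transcript("T", "c", "+", ((1, 12),), "ATGCGTCTGTAA", protein_sequence="MRK")


class TestAnnotateConsequence:
    def test_cgt_to_tgt_is_missense_arg_to_cys(self):
        # codon 2 = CGT (Arg); C>T at its first base gives TGT (Cys)
        t = make_transcript("ATGCGTCTGTAA")
        v = VariantCall("chrX", 14, "C", "T", "het")
        out = annotate_consequence(v, t)
        assert out.consequence == "missense"
        assert out.protein_change == "p.R2C"

    def test_ctg_to_cta_is_synonymous(self):
        # codon 3 = CTG (Leu); G>A at its third base gives CTA (Leu)
        t = make_transcript("ATGCGTCTGTAA")
        v = VariantCall("chrX", 19, "G", "A", "het")
        out = annotate_consequence(v, t)
        assert out.consequence == "synonymous"
        assert out.protein_change == "p.L3="

    def test_nonsense_labelled_with_stop(self):
        # codon 2 CGT: C>T at second base -> CAT? no; use CGA via A? plant TAT->TAA style
        t = make_transcript("ATGTATCTGTAA")
        # codon 2 = TAT (Tyr); T>A at third base gives TAA (stop)
        v = VariantCall("chrX", 16, "T", "A", "het")
        out = annotate_consequence(v, t)
        assert out.consequence == "nonsense"
        assert out.protein_change == "p.Y2*"

    def test_reference_mismatch_names_position(self):
        t = make_transcript("ATGCGTCTGTAA")
        v = VariantCall("chrX", 14, "G", "A", "het")
        with pytest.raises(ReferenceMismatchError, match="14"):
            annotate_consequence(v, t)

    def test_utr_and_out_of_span(self):
        t = make_transcript("ATGCGTCTGTAA")
        out = annotate_consequence(VariantCall("chrX", 5, "A", "G", "het"), t)
        # ref check does not apply outside the CDS
        assert out.consequence == "utr" and out.protein_change is None
        with pytest.raises(ValueError, match="span"):
            annotate_consequence(VariantCall("chrX", 500, "A", "G", "het"), t)

    def test_splice_region_vs_deep_intron(self, toy_plus):
        t = toy_plus.transcript
        # exon1 ends at 121; 122-123 splice region, 135 deep intron
        for pos, expect in ((123, "splice_region"), (135, "noncoding")):
            ref = toy_plus.genome["chrT"][pos - 1]
            alt = "A" if ref != "A" else "G"
            out = annotate_consequence(VariantCall("chrT", pos, ref, alt, "het"), t)
            assert out.consequence == expect

    def test_brute_force_oracle_all_cds_snvs(self, toy_plus):
        """Codon-level annotation agrees with translate-whole-protein-and-diff."""
        data = toy_plus
        t = data.transcript
        cds = t.cds_sequence
        wt_aa = str(Seq(cds).translate())
        checked = 0
        for idx in range(len(cds)):
            pos = _genomic_pos(t, idx)
            for alt in "ACGT":
                if alt == cds[idx]:
                    continue
                mut = cds[:idx] + alt + cds[idx + 1 :]
                mut_aa = str(Seq(mut).translate())
                diffs = [k for k in range(len(wt_aa)) if wt_aa[k] != mut_aa[k]]
                g_ref = cds[idx] if t.strand == "+" else reverse_complement(cds[idx])
                g_alt = alt if t.strand == "+" else reverse_complement(alt)
                out = annotate_consequence(
                    VariantCall("chrT", pos, g_ref, g_alt, "het"), t
                )
                if not diffs:
                    assert out.consequence == "synonymous"
                elif mut_aa[diffs[0]] == "*":
                    assert out.consequence == "nonsense"
                else:
                    assert out.consequence == "missense"
                checked += 1
        assert checked == 3 * len(cds)

    def test_minus_strand_mirror_gives_same_protein_change(self, toy_plus, toy_minus):
        """'+' and '-' constructions of the same CDS annotate identically."""
        assert toy_plus.transcript.cds_sequence == toy_minus.transcript.cds_sequence
        plus = {
            toy_plus.expected[k]
            for k in toy_plus.expected
            if toy_plus.expected[k][1] is not None
        }
        minus = {
            toy_minus.expected[k]
            for k in toy_minus.expected
            if toy_minus.expected[k][1] is not None
        }
        assert plus == minus


def _genomic_pos(t, idx):
    offset = 0
    for s, e in t.cds_segments:
        length = e - s + 1
        if idx < offset + length:
            return s + (idx - offset) if t.strand == "+" else e - (idx - offset)
        offset += length
    raise AssertionError


class TestFilterRareMissense:
    def _v(self, **kw):
        base = dict(
            chrom="c", pos=1, ref="A", alt="G", genotype="het", gene="LRP5",
            maf=0.005, consequence="missense", protein_change="p.K1R",
        )
        base.update(kw)
        return VariantCall(**base)

    def test_rare_het_missense_in_panel_kept(self):
        assert filter_rare_missense([self._v()], genes={"LRP5"}) != []

    @pytest.mark.parametrize(
        "kw",
        [
            dict(consequence="synonymous", protein_change="p.K1="),
            dict(genotype="hom_alt"),
            dict(gene="OTHER"),
            dict(maf=0.05),
            dict(maf=0.01),  # boundary: filter is strict (< 1%)
        ],
    )
    def test_each_failing_predicate_drops(self, kw):
        assert filter_rare_missense([self._v(**kw)], genes={"LRP5"}) == []

    def test_missing_maf_counts_as_rare(self):
        assert filter_rare_missense([self._v(maf=None)], genes={"LRP5"}) != []

    def test_count_matches_predicate_oracle(self, toy_plus):
        from varodds import annotate_consequence

        ann = [annotate_consequence(v, toy_plus.transcript) for v in toy_plus.variants]
        kept = filter_rare_missense(ann, genes={"LRP5"})
        oracle = [
            v
            for v in ann
            if v.consequence == "missense"
            and v.genotype == "het"
            and v.gene == "LRP5"
            and (v.maf is None or v.maf < 0.01)
        ]
        assert len(kept) == toy_plus.n_qualifying == len(oracle)
        assert kept == oracle  # order preserved

    def test_idempotent(self, toy_plus):
        from varodds import annotate_consequence

        ann = [annotate_consequence(v, toy_plus.transcript) for v in toy_plus.variants]
        once = filter_rare_missense(ann, genes={"LRP5"})
        assert filter_rare_missense(once, genes={"LRP5"}) == once

    def test_indels_rejected_at_construction(self):
        with pytest.raises(ValueError, match="SNV"):
            VariantCall("c", 1, "AT", "A", "het")
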