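"""Transcript models, SNV consequence annotation and rare-missense filtering.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention). Only
single-nucleotide substitutions are supported; indels are rejected. The
standard nuclear genetic code (NCBI translation table 1) is used, via
Biopython.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq, reverse_complement

__all__ = [
    "Transcript",
    "VariantCall",
    "ReferenceMismatchError",
    "annotate_consequence",
    "filter_rare_missense",
    "CONSEQUENCES",
    "GENOTYPES",
]

CONSEQUENCES = ("synonymous", "missense", "nonsense", "noncoding", "splice_region", "utr")
GENOTYPES = ("het", "hom_ref", "hom_alt")

_NT = set("ACGT")
_SPLICE_WINDOW = 2  # nt into the intron still called splice_region


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the transcript sequence."""

    def __init__(self, pos: int, expected: str, observed: str):
        self.pos = pos
        super().__init__(
            f"reference mismatch at position {pos}: transcript has {expected!r}, "
            f"variant REF is {observed!r}"
        )


@dataclass(frozen=True)
class Transcript:
    """A coding transcript: spliced CDS plus its genomic segment layout.

    ``cds_segments`` are (start, end) genomic intervals, 1-based inclusive,
    in *transcription* order: ascending genomic coordinates on '+', descending
    on '-'. ``cds_sequence`` is the spliced coding-strand sequence in frame 0
    and includes the terminal stop codon. ``protein_sequence`` is derived from
    the CDS when not supplied.

    ``tx_start``/``tx_end`` optionally extend the transcript span beyond the
    CDS (UTRs); they default to the CDS genomic extremes.
    """

    id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_sequence: str
    protein_sequence: str = ""
    tx_start: int | None = None
    tx_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = tuple((int(s), int(e)) for s, e in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        if not segs:
            raise ValueError("transcript requires at least one CDS segment")
        for s, e in segs:
            if s > e:
                raise ValueError(f"CDS segment ({s}, {e}) has start > end")
        genomic = segs if self.strand == "+" else segs[::-1]
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError("CDS segments overlap or are out of transcription order")
        cds = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", cds)
        total = sum(e - s + 1 for s, e in segs)
        if total != len(cds):
            raise ValueError(f"CDS segments span {total} nt but cds_sequence has {len(cds)}")
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        aa = str(Seq(cds).translate())
        if not aa.endswith("*") or "*" in aa[:-1]:
            raise ValueError("CDS must translate to protein plus a single terminal stop")
        if self.protein_sequence:
            if self.protein_sequence != aa[:-1]:
                raise ValueError("protein_sequence does not match translated CDS")
        else:
            object.__setattr__(self, "protein_sequence", aa[:-1])
        lo = min(s for s, _ in segs)
        hi = max(e for _, e in segs)
        object.__setattr__(self, "tx_start", lo if self.tx_start is None else int(self.tx_start))
        object.__setattr__(self, "tx_end", hi if self.tx_end is None else int(self.tx_end))
        if self.tx_start > lo or self.tx_end < hi:
            raise ValueError("transcript span must contain all CDS segments")

    @property
    def cds_start(self) -> int:
        return min(s for s, _ in self.cds_segments)

    @property
    def cds_end(self) -> int:
        return max(e for _, e in self.cds_segments)

    def cds_index(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
        offset = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None


@dataclass
class VariantCall:
    """One single-nucleotide variant with genotype and annotation slots."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    gene: str = ""
    maf: float | None = None
    consequence: str | None = None
    protein_change: str | None = None

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only SNVs are supported; got ref={self.ref!r} alt={self.alt!r} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.ref not in _NT or self.alt not in _NT:
            raise ValueError(f"alleles must be A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


def _hgvs_p(aa_ref: str, codon_number: int, aa_alt: str) -> str:
    if aa_ref == aa_alt:
        return f"p.{aa_ref}{codon_number}="
    return f"p.{aa_ref}{codon_number}{aa_alt}"


def annotate_consequence(v: VariantCall, t: Transcript) -> VariantCall:
    """Annotate ``v`` with its coding consequence and HGVS p. label.

    Positions in the CDS are classified synonymous/missense/nonsense by codon
    substitution; intronic positions within 2 nt of a CDS segment edge are
    splice_region, deeper intronic positions noncoding, and span positions
    outside the CDS extremes utr. On '-' transcripts the alleles are
    complemented before codon lookup.
    """
    if v.chrom != t.chrom:
        raise ValueError(f"variant chrom {v.chrom!r} does not match transcript {t.chrom!r}")
    if not (t.tx_start <= v.pos <= t.tx_end):
        raise ValueError(
            f"position {v.pos} outside transcript span {t.tx_start}-{t.tx_end}"
        )

    idx = t.cds_index(v.pos)
    if idx is None:
        if v.pos < t.cds_start or v.pos > t.cds_end:
            cons = "utr"
        else:
            near_edge = any(
                0 < v.pos - e <= _SPLICE_WINDOW or 0 < s - v.pos <= _SPLICE_WINDOW
                for s, e in t.cds_segments
            )
            cons = "splice_region" if near_edge else "noncoding"
        return dataclasses.replace(v, consequence=cons, protein_change=None)

    cds_ref = v.ref if t.strand == "+" else reverse_complement(v.ref)
    cds_alt = v.alt if t.strand == "+" else reverse_complement(v.alt)
    if t.cds_sequence[idx] != cds_ref:
        raise ReferenceMismatchError(v.pos, expected=t.cds_sequence[idx], observed=v.ref)

    codon_i = idx // 3
    within = idx % 3
    codon = t.cds_sequence[codon_i * 3 : codon_i * 3 + 3]
    new_codon = codon[:within] + cds_alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())

    if aa_ref == aa_alt:
        cons = "synonymous"
    elif aa_alt == "*":
        cons = "nonsense"
    else:
        # includes stop-loss (aa_ref == '*'), reported as a missense-type change
        cons = "missense"
    change = _hgvs_p(aa_ref, codon_i + 1, aa_alt)
    return dataclasses.replace(v, consequence=cons, protein_change=change)


def filter_rare_missense(
    variants: Sequence[VariantCall],
    maf_max: float = 0.01,
    genes: Iterable[str] | None = None,
) -> list[VariantCall]:
    """Keep heterozygous missense variants in the gene panel with MAF < ``maf_max``.

    A missing MAF counts as rare: novel variants have no population frequency
    record and must not be excluded. Input order is preserved; the filter is
    idempotent.
    """
    gene_set = set(genes) if genes is not None else None

    def keep(v: VariantCall) -> bool:
        if v.consequence != "missense" or v.genotype != "het":
            return False
        if gene_set is not None and v.gene not in gene_set:
            return False
        return v.maf is None or v.maf < maf_max

    return [v for v in variants if keep(v)]
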