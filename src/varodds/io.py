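"""File I/O: VCF (pysam), GFF3 (gffutils), FASTA (Biopython), TSV tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .descriptors import EvidenceContext, PredictorCalls
from .selfalign import ConservationProfile, UnitAlignment
from .variants import Transcript, VariantCall

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_maf_tsv",
    "read_fasta",
    "write_fasta",
    "read_transcript",
    "write_transcript_gff3",
    "variants_to_frame",
    "write_variants_tsv",
    "read_predictors_tsv",
    "write_predictors_tsv",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_units_tsv",
    "write_alignment_fasta",
    "write_profile_tsv",
]

_GT_CODE = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}


def read_vcf(path, maf: Mapping[str, float] | None = None) -> list[VariantCall]:
    """Read SNVs from a VCF (v4.2, sites + GT of the first sample).

    MAF is taken from INFO key ``AF`` when present; a sidecar mapping
    (``"chrom:pos:ref:alt"`` -> maf, e.g. from :func:`read_maf_tsv`)
    overrides it. Gene symbols come from INFO key ``GENE`` when present.
    """
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                genotype = "het"
                if samples:
                    gt = rec.samples[samples[0]].get("GT")
                    if gt is not None and None not in gt:
                        n_alt = sum(1 for a in gt if a and a > 0)
                        genotype = ("hom_ref", "het", "hom_alt")[min(n_alt, 2)]
                af = rec.info.get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                if maf is not None and key in maf:
                    af = maf[key]
                gene = rec.info.get("GENE", "")
                out.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotype=genotype,
                        gene=str(gene) if gene else "",
                        maf=float(af) if af is not None else None,
                    )
                )
    return out


def write_vcf(
    variants: Sequence[VariantCall],
    path,
    contigs: Mapping[str, int],
    sample: str = "S1",
) -> None:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("AF", 1, "Float", "Allele frequency")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt)
            )
            if v.maf is not None:
                rec.info["AF"] = v.maf
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.samples[sample]["GT"] = _GT_CODE[v.genotype]
            vf.write(rec)


def read_maf_tsv(path) -> dict[str, float]:
    """Sidecar MAF table: columns ``variant_key`` (chrom:pos:ref:alt) and ``maf``."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["variant_key"].astype(str), df["maf"].astype(float)))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_transcript(gff3_path, fasta_path, transcript_id: str | None = None) -> Transcript:
    """Build a Transcript from a GFF3 (CDS features) and a FASTA.

    The FASTA may hold either the genome contig (record named after the
    chromosome) or the already-spliced CDS (record named after the
    transcript).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    cds_feats = [f for f in db.features_of_type("CDS")]
    if transcript_id is not None:
        cds_feats = [
            f for f in cds_feats
            if transcript_id in f.attributes.get("Parent", [])
            or transcript_id in f.attributes.get("ID", [])
        ]
    if not cds_feats:
        raise ValueError("no CDS features found in GFF3")
    chrom = cds_feats[0].seqid
    strand = cds_feats[0].strand
    parent = transcript_id or (cds_feats[0].attributes.get("Parent", ["tx"])[0])
    tx_start = tx_end = None
    for f in db.features_of_type(("mRNA", "transcript")):
        if transcript_id is None or f.id == transcript_id:
            tx_start, tx_end = f.start, f.end
            break

    segs = sorted(((f.start, f.end) for f in cds_feats), reverse=(strand == "-"))
    seqs = read_fasta(fasta_path)
    if chrom in seqs:
        genome = seqs[chrom]
        chunks = []
        for s, e in segs:
            piece = genome[s - 1 : e]
            chunks.append(piece if strand == "+" else reverse_complement(piece))
        cds_sequence = "".join(chunks)
    elif parent in seqs:
        cds_sequence = seqs[parent]
    else:
        raise ValueError(
            f"FASTA contains neither contig {chrom!r} nor transcript {parent!r}"
        )
    return Transcript(
        id=parent,
        chrom=chrom,
        strand=strand,
        cds_segments=tuple(segs),
        cds_sequence=cds_sequence,
        tx_start=tx_start,
        tx_end=tx_end,
    )


def write_transcript_gff3(t: Transcript, path, gene: str = "") -> None:
    lines = ["##gff-version 3"]
    lines.append(
        "\t".join(
            [
                t.chrom, "varodds", "mRNA", str(t.tx_start), str(t.tx_end),
                ".", t.strand, ".", f"ID={t.id}" + (f";gene={gene}" if gene else ""),
            ]
        )
    )
    genomic = sorted(t.cds_segments)
    phase = 0
    # phase must follow transcription order
    ordered = t.cds_segments
    phases = {}
    for s, e in ordered:
        phases[(s, e)] = phase
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    for s, e in genomic:
        lines.append(
            "\t".join(
                [
                    t.chrom, "varodds", "CDS", str(s), str(e), ".", t.strand,
                    str(phases[(s, e)]), f"ID=cds-{t.id};Parent={t.id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "genotype": v.genotype,
                "gene": v.gene,
                "maf": v.maf,
                "consequence": v.consequence,
                "protein_change": v.protein_change,
            }
            for v in variants
        ]
    )


def write_variants_tsv(variants: Iterable[VariantCall], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def write_predictors_tsv(predictors: Mapping[str, PredictorCalls], path) -> None:
    pd.DataFrame(
        [
            {"variant": k, "polyphen": p.polyphen, "sift": p.sift,
             "pmut": p.pmut, "ddg": p.ddg}
            for k, p in predictors.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_predictors_tsv(path) -> dict[str, PredictorCalls]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["variant"]): PredictorCalls(
            polyphen=str(r["polyphen"]), sift=str(r["sift"]),
            pmut=str(r["pmut"]), ddg=float(r["ddg"]), variant=str(r["variant"]),
        )
        for _, r in df.iterrows()
    }


_EVIDENCE_COLS = (
    "literature_pathogenic",
    "dbsnp_low_freq_no_functional",
    "prior_annotation_in_db",
    "in_functional_domain",
    "in_structured_domain",
    "on_linear_motif",
    "conserved_position",
    "low_complexity_context",
)


def write_evidence_tsv(evidence: Mapping[str, EvidenceContext], path) -> None:
    pd.DataFrame(
        [
            {"variant": k, **{c: int(getattr(e, c)) for c in _EVIDENCE_COLS}}
            for k, e in evidence.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path) -> dict[str, EvidenceContext]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["variant"]): EvidenceContext(
            **{c: bool(int(r[c])) for c in _EVIDENCE_COLS}, variant=str(r["variant"])
        )
        for _, r in df.iterrows()
    }


def read_units_tsv(path) -> dict[str, list[tuple[int, int]]]:
    """Unit-boundary TSV: columns protein_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, int]]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["protein_id"]), []).append((int(r["start"]), int(r["end"])))
    return out


def write_alignment_fasta(aln: UnitAlignment, path, names: Sequence[str] | None = None) -> None:
    names = names or [f"unit_{i + 1}" for i in range(len(aln.rows))]
    write_fasta(dict(zip(names, aln.rows)), path)


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    pd.DataFrame(
        {
            "column": range(1, len(profile.scores) + 1),
            "score": profile.scores,
            "consensus": list(profile.consensus),
        }
    ).to_csv(path, sep="\t", index=False)
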