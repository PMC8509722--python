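"""Synthetic-data generators with planted truth for every pipeline stage.

All generators are pure functions of a :class:`SimulationConfig` (seed
included): the same config reproduces byte-identical outputs. Random streams
are split per generator with fixed offsets from the single seed, so adding a
generator never perturbs existing outputs.

Defaults emulate the study conditions the pipeline targets: a cohort of 128
men with low bone mass (ages ~ N(41.6, 8.7) truncated to [18, 60], DXA
scores with the published cohort moments) of whom 11 carry a rare variant;
variant tables mixing benign-profile and pathogenic-profile variants whose
predictor calls and evidence flags are drawn from class-conditional
positivity probabilities (0.8 given pathogenic, 0.1 given benign); and
repeat proteins built from a random consensus unit with a per-position
substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement
from scipy import stats

from .cohort import CohortSubject
from .descriptors import EvidenceContext, PredictorCalls
from .variants import Transcript, VariantCall

__all__ = [
    "SimulationConfig",
    "VariantTables",
    "ToyTranscriptData",
    "gen_cohort",
    "gen_variant_set",
    "gen_repeat_protein",
    "gen_toy_transcript",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# per-generator stream offsets
_STREAM_COHORT = 1
_STREAM_VARIANTS = 2
_STREAM_REPEATS = 3
_STREAM_TRANSCRIPT = 4

#: published cohort DXA moments (mean, SD) used as generator defaults
DEFAULT_DXA = {
    "bmd_l": (0.82, 0.07),
    "t_l": (-2.5, 0.55),
    "z_l": (-2.48, 0.59),
    "bmd_th": (0.88, 0.11),
    "t_th": (-1.07, 0.79),
    "z_th": (-0.99, 0.72),
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # cohort
    n_subjects: int = 128
    carrier_fraction: float = 11 / 128
    age_mean: float = 41.6
    age_sd: float = 8.7
    dxa_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DXA)
    )
    # variant table
    n_variants: int = 500
    pathogenic_fraction: float = 0.5
    p_pathogenic: float = 0.8
    p_benign: float = 0.1
    # repeat protein
    unit_length: int = 60
    n_units: int = 8
    unit_mut_rate: float = 0.2

    def __post_init__(self):
        for name in ("carrier_fraction", "pathogenic_fraction", "p_pathogenic",
                     "p_benign", "unit_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_subjects", "n_variants", "unit_length", "n_units"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rng(cfg: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, cfg.seed])


def gen_cohort(cfg: SimulationConfig) -> list[CohortSubject]:
    """Simulate the cohort: truncated-normal ages, normal DXA scores.

    The carrier count is assigned deterministically as
    ``round(carrier_fraction * n_subjects)`` (not Bernoulli) so fixture-level
    counts are exact; which subjects carry is randomized.
    """
    rng = _rng(cfg, _STREAM_COHORT)
    n = cfg.n_subjects
    if n == 0:
        return []
    lo, hi = 18.0, 60.0
    ages = stats.truncnorm.rvs(
        (lo - cfg.age_mean) / cfg.age_sd,
        (hi - cfg.age_mean) / cfg.age_sd,
        loc=cfg.age_mean,
        scale=cfg.age_sd,
        size=n,
        random_state=rng,
    )
    dxa = {
        name: rng.normal(mu, sd, size=n) for name, (mu, sd) in cfg.dxa_params.items()
    }
    n_carriers = round(cfg.carrier_fraction * n)
    carrier_idx = set(rng.choice(n, size=n_carriers, replace=False).tolist())
    return [
        CohortSubject(
            id=f"S{i + 1:04d}",
            age=float(ages[i]),
            bmd_l=float(dxa["bmd_l"][i]),
            t_l=float(dxa["t_l"][i]),
            z_l=float(dxa["z_l"][i]),
            bmd_th=float(dxa["bmd_th"][i]),
            t_th=float(dxa["t_th"][i]),
            z_th=float(dxa["z_th"][i]),
            carrier=i in carrier_idx,
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class VariantTables:
    """Simulated classifier inputs plus the sidecar truth labels.

    ``truth`` is kept separate from the tables the pipeline consumes so that
    planted labels never leak into classifier inputs.
    """

    labels: tuple[str, ...]
    predictors: dict[str, PredictorCalls]
    evidence: dict[str, EvidenceContext]
    truth: pd.Series
    variants: pd.DataFrame


def gen_variant_set(cfg: SimulationConfig) -> VariantTables:
    """Simulate a variant table with class-conditional predictor/evidence draws.

    ``round(pathogenic_fraction * n_variants)`` variants are pathogenic-profile:
    each categorical predictor is damaging, and each evidence flag positive,
    with probability ``p_pathogenic`` (benign-profile variants use
    ``p_benign``). Literature evidence supersedes the dbSNP frequency flag.
    All MAFs are below 1%.
    """
    rng = _rng(cfg, _STREAM_VARIANTS)
    n = cfg.n_variants
    n_path = round(cfg.pathogenic_fraction * n)
    is_path = np.zeros(n, dtype=bool)
    is_path[rng.choice(n, size=n_path, replace=False)] = True

    labels = tuple(f"p.A{i + 1}V" for i in range(n))
    predictors: dict[str, PredictorCalls] = {}
    evidence: dict[str, EvidenceContext] = {}
    rows = []
    for i, label in enumerate(labels):
        p = cfg.p_pathogenic if is_path[i] else cfg.p_benign
        polyphen = (
            rng.choice(["possibly_damaging", "probably_damaging"])
            if rng.random() < p
            else "benign"
        )
        sift = "not_tolerated" if rng.random() < p else "tolerated"
        pmut = "disease" if rng.random() < p else "neutral"
        ddg = -abs(rng.normal(0.7, 0.4))
        predictors[label] = PredictorCalls(
            polyphen=str(polyphen), sift=sift, pmut=pmut, ddg=float(ddg), variant=label
        )
        literature = rng.random() < p
        dbsnp = (not literature) and rng.random() < p
        evidence[label] = EvidenceContext(
            literature_pathogenic=literature,
            dbsnp_low_freq_no_functional=dbsnp,
            prior_annotation_in_db=rng.random() < p,
            in_functional_domain=rng.random() < p,
            in_structured_domain=rng.random() < p,
            on_linear_motif=rng.random() < p,
            conserved_position=rng.random() < p,
            low_complexity_context=rng.random() < p,
            variant=label,
        )
        rows.append(
            {
                "variant": label,
                "gene": "LRP5",
                "genotype": "het",
                "maf": float(rng.uniform(0.0, 0.0099)),
                "consequence": "missense",
            }
        )
    truth = pd.Series(
        np.where(is_path, "pathogenic", "benign"), index=list(labels), name="truth"
    )
    return VariantTables(
        labels=labels,
        predictors=predictors,
        evidence=evidence,
        truth=truth,
        variants=pd.DataFrame(rows),
    )


def gen_repeat_protein(cfg: SimulationConfig) -> tuple[str, list[tuple[int, int]], str]:
    """Simulate a repeat protein: mutated copies of a random consensus unit.

    Returns ``(protein, boundaries, consensus)``. Each of ``n_units`` copies
    of the consensus is substituted per position with probability
    ``unit_mut_rate`` (always to a different residue), then the copies are
    concatenated; boundaries are exact.
    """
    if cfg.n_units < 2:
        raise ValueError("n_units must be >= 2 for self-analysis")
    rng = _rng(cfg, _STREAM_REPEATS)
    consensus = "".join(rng.choice(list(_AA), size=cfg.unit_length))
    units = []
    for _ in range(cfg.n_units):
        chars = list(consensus)
        for j in range(cfg.unit_length):
            if rng.random() < cfg.unit_mut_rate:
                alternatives = [a for a in _AA if a != chars[j]]
                chars[j] = alternatives[rng.integers(len(alternatives))]
        units.append("".join(chars))
    protein = "".join(units)
    boundaries = [
        (i * cfg.unit_length + 1, (i + 1) * cfg.unit_length) for i in range(cfg.n_units)
    ]
    return protein, boundaries, consensus


@dataclass(frozen=True)
class ToyTranscriptData:
    """A small multi-exon transcript with planted variants and their truth."""

    transcript: Transcript
    genome: dict[str, str]
    variants: tuple[VariantCall, ...]
    #: (pos, ref, alt) -> (consequence, protein_change or None)
    expected: dict[tuple[int, str, str], tuple[str, str | None]]
    n_qualifying: int


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_NT), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _codon_effect(cds: str, idx: int, alt_cds: str) -> tuple[str, str]:
    """Consequence and HGVS p. of substituting ``alt_cds`` at CDS offset ``idx``."""
    ci, within = divmod(idx, 3)
    codon = cds[ci * 3 : ci * 3 + 3]
    new = codon[:within] + alt_cds + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new).translate())
    if aa_ref == aa_alt:
        return "synonymous", f"p.{aa_ref}{ci + 1}="
    if aa_alt == "*":
        return "nonsense", f"p.{aa_ref}{ci + 1}*"
    return "missense", f"p.{aa_ref}{ci + 1}{aa_alt}"


def gen_toy_transcript(
    cfg: SimulationConfig, strand: str = "+", gene: str = "LRP5"
) -> ToyTranscriptData:
    """Simulate a 3-exon transcript plus 20 planted variants.

    Exactly 7 variants satisfy the rare-missense filter (missense AND het AND
    panel gene AND MAF < 1% or missing); the other 13 each fail at least one
    predicate (synonymous, homozygous, common, off-panel gene, or non-coding
    position). Expected annotations are recorded for every planted variant.
    """
    rng = _rng(cfg, _STREAM_TRANSCRIPT)
    chrom = "chrT"
    n_codons = 20
    cds = _random_cds(rng, n_codons)

    genomic_segments = [(101, 121), (151, 168), (201, 221)]  # 21+18+21 = 60 nt
    tx_start, tx_end = 81, 241
    genome_len = 300
    genome = list("".join(rng.choice(list(_NT), size=genome_len)))

    if strand == "+":
        segments = genomic_segments
    else:
        segments = genomic_segments[::-1]

    # plant the spliced CDS into the genome (transcription order)
    offset = 0
    pos_of_idx: dict[int, int] = {}
    for s, e in segments:
        length = e - s + 1
        chunk = cds[offset : offset + length]
        if strand == "+":
            genome[s - 1 : e] = list(chunk)
            for k in range(length):
                pos_of_idx[offset + k] = s + k
        else:
            genome[s - 1 : e] = list(reverse_complement(chunk))
            for k in range(length):
                pos_of_idx[offset + k] = e - k
        offset += length
    genome_str = "".join(genome)

    transcript = Transcript(
        id="TOY1",
        chrom=chrom,
        strand=strand,
        cds_segments=tuple(segments),
        cds_sequence=cds,
        tx_start=tx_start,
        tx_end=tx_end,
    )

    def genomic_alleles(idx: int, alt_cds: str) -> tuple[int, str, str]:
        pos = pos_of_idx[idx]
        if strand == "+":
            return pos, cds[idx], alt_cds
        return pos, reverse_complement(cds[idx]), reverse_complement(alt_cds)

    # classify every possible CDS substitution, then draw the planted mix
    missense_sites: list[tuple[int, str]] = []
    synonymous_sites: list[tuple[int, str]] = []
    for idx in range(len(cds)):
        for alt in _NT:
            if alt == cds[idx]:
                continue
            cons, _ = _codon_effect(cds, idx, alt)
            if cons == "missense":
                missense_sites.append((idx, alt))
            elif cons == "synonymous":
                synonymous_sites.append((idx, alt))
    rng.shuffle(missense_sites)
    rng.shuffle(synonymous_sites)
    mis = iter(missense_sites)
    syn = iter(synonymous_sites)

    variants: list[VariantCall] = []
    expected: dict[tuple[int, str, str], tuple[str, str | None]] = {}

    def add_coding(site, genotype: str, g: str, maf):
        idx, alt = site
        pos, g_ref, g_alt = genomic_alleles(idx, alt)
        cons, change = _codon_effect(cds, idx, alt)
        variants.append(
            VariantCall(chrom=chrom, pos=pos, ref=g_ref, alt=g_alt,
                        genotype=genotype, gene=g, maf=maf)
        )
        expected[(pos, g_ref, g_alt)] = (cons, change)

    def add_noncoding(pos: int, cons: str):
        ref = genome_str[pos - 1]
        alt = rng.choice([n for n in _NT if n != ref])
        variants.append(
            VariantCall(chrom=chrom, pos=pos, ref=ref, alt=str(alt),
                        genotype="het", gene=gene, maf=float(rng.uniform(0, 0.0099)))
        )
        expected[(pos, ref, str(alt))] = (cons, None)

    # 7 qualifying: missense, het, panel gene, rare (one with missing MAF)
    for k in range(7):
        maf = None if k == 0 else float(rng.uniform(0, 0.0099))
        add_coding(next(mis), "het", gene, maf)
    # 13 non-qualifying
    for _ in range(3):
        add_coding(next(syn), "het", gene, float(rng.uniform(0, 0.0099)))
    for _ in range(2):
        add_coding(next(mis), "hom_alt", gene, float(rng.uniform(0, 0.0099)))
    for _ in range(2):
        add_coding(next(mis), "het", gene, float(rng.uniform(0.02, 0.2)))
    for _ in range(2):
        add_coding(next(mis), "het", "OTHER", float(rng.uniform(0, 0.0099)))
    # intronic: deep (noncoding) and near-boundary (splice_region); plus UTR
    add_noncoding(135, "noncoding")
    add_noncoding(185, "noncoding")
    add_noncoding(123, "splice_region")
    add_noncoding(90, "utr")

    return ToyTranscriptData(
        transcript=transcript,
        genome={chrom: genome_str},
        variants=tuple(variants),
        expected=expected,
        n_qualifying=7,
    )
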