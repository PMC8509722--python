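"""The eight-descriptor evidence engine.

Each candidate variant is summarized by eight binary descriptors, in this
fixed order:

  d1  sequence conservation at the position
  d2  position inside an annotated functional domain
  d3  low local sequence complexity
  d4  position inside a structured (ordered) domain
  d5  position on/near a functional linear motif
  d6  agreement among categorical in-silico predictors
  d7  previous pathogenic annotation in a public database
  d8  pathogenicity data in the literature

d1, d3, d5 and d6 can be computed here from sequence context and predictor
calls; the others are ingested as curated flags (database / literature /
structure lookups are inputs, not computations).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "PredictorCalls",
    "EvidenceContext",
    "DescriptorProfile",
    "conservation_descriptor",
    "complexity_descriptor",
    "motif_descriptor",
    "find_ppxsp_motifs",
    "predictor_damage_count",
    "build_profile",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

POLYPHEN_LEVELS = ("benign", "possibly_damaging", "probably_damaging")
SIFT_LEVELS = ("tolerated", "not_tolerated")
PMUT_LEVELS = ("neutral", "disease")

#: entropy below this many bits marks a low-complexity window
LOW_COMPLEXITY_BITS = 2.0


@dataclass(frozen=True)
class PredictorCalls:
    """Categorical pathogenicity predictions plus a stability ΔΔG.

    ``ddg`` (kcal/mol, negative = destabilizing) is carried for reporting but
    does not enter the damage count: in practice rare missense changes are
    almost uniformly predicted to decrease stability, so the sign carries no
    discrimination.
    """

    polyphen: str
    sift: str
    pmut: str
    ddg: float
    variant: str = ""

    def __post_init__(self):
        if self.polyphen not in POLYPHEN_LEVELS:
            raise ValueError(f"polyphen must be one of {POLYPHEN_LEVELS}, got {self.polyphen!r}")
        if self.sift not in SIFT_LEVELS:
            raise ValueError(f"sift must be one of {SIFT_LEVELS}, got {self.sift!r}")
        if self.pmut not in PMUT_LEVELS:
            raise ValueError(f"pmut must be one of {PMUT_LEVELS}, got {self.pmut!r}")
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")


@dataclass(frozen=True)
class EvidenceContext:
    """Curated per-variant evidence flags (database/literature/structure)."""

    literature_pathogenic: bool = False
    dbsnp_low_freq_no_functional: bool = False
    prior_annotation_in_db: bool = False
    in_functional_domain: bool = False
    in_structured_domain: bool = False
    on_linear_motif: bool = False
    conserved_position: bool = False
    low_complexity_context: bool = False
    variant: str = ""

    def __post_init__(self):
        if self.literature_pathogenic and self.dbsnp_low_freq_no_functional:
            raise ValueError(
                "literature_pathogenic and dbsnp_low_freq_no_functional are mutually "
                "exclusive (literature evidence supersedes the dbSNP frequency class)"
            )


@dataclass(frozen=True)
class DescriptorProfile:
    """The eight binary descriptors for one variant, in canonical order."""

    d1: int
    d2: int
    d3: int
    d4: int
    d5: int
    d6: int
    d7: int
    d8: int
    source_variant: str = ""

    def __post_init__(self):
        for name in ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.d1, self.d2, self.d3, self.d4, self.d5, self.d6, self.d7, self.d8)

    @property
    def agreement(self) -> float:
        """Fraction of the eight descriptors that are positive."""
        return sum(self.as_tuple()) / 8.0


def conservation_descriptor(
    column: Sequence[str], threshold: float = 0.9
) -> tuple[float, int]:
    """Score one alignment column: modal non-gap residue frequency.

    Returns ``(score, flag)`` where flag is 1 iff score >= threshold. An
    all-gap column scores 0.
    """
    if not column:
        raise ValueError("column must be non-empty")
    for sym in column:
        if sym != "-" and sym not in AMINO_ACIDS:
            raise ValueError(f"unknown residue symbol {sym!r}")
    residues = [s for s in column if s != "-"]
    if not residues:
        return 0.0, 0
    score = Counter(residues).most_common(1)[0][1] / len(residues)
    return score, int(score >= threshold)


def complexity_descriptor(window: str) -> tuple[float, int]:
    """Shannon entropy (bits) of residue frequencies in a sequence window.

    Flag is 1 (low complexity, pathogenicity-relevant context) iff the
    entropy is below 2.0 bits. Windows shorter than 5 residues are rejected.
    """
    if len(window) < 5:
        raise ValueError(f"window must be at least 5 residues, got {len(window)}")
    for sym in window:
        if sym not in AMINO_ACIDS:
            raise ValueError(f"unknown residue symbol {sym!r}")
    n = len(window)
    entropy = -sum(
        (c / n) * math.log2(c / n) for c in Counter(window).values()
    )
    return entropy, int(entropy < LOW_COMPLEXITY_BITS)


def motif_descriptor(
    protein_pos: int,
    motifs: Sequence[tuple[int, int]],
    proximity: int = 5,
) -> int:
    """1 iff ``protein_pos`` falls inside a motif or within ``proximity`` of one."""
    return int(
        any(start - proximity <= protein_pos <= end + proximity for start, end in motifs)
    )


_PPXSP = re.compile(r"PP[A-Z]SP")


def find_ppxsp_motifs(protein: str) -> list[tuple[int, int]]:
    """1-based inclusive intervals of P-P-x-S-P motifs (non-overlapping scan).

    The pattern covers both the PPSP and PPPSP spellings of the LRP-family
    phosphorylation motif.
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    return [(m.start() + 1, m.start() + 5) for m in _PPXSP.finditer(protein.upper())]


def predictor_damage_count(p: PredictorCalls) -> int:
    """Number of damaging calls among the three categorical predictors (0-3)."""
    return (
        int(p.polyphen in ("possibly_damaging", "probably_damaging"))
        + int(p.sift == "not_tolerated")
        + int(p.pmut == "disease")
    )


def build_profile(
    v,
    p: PredictorCalls,
    e: EvidenceContext,
    agreement_min: int = 2,
) -> DescriptorProfile:
    """Assemble the eight-descriptor profile for one variant.

    ``v`` is the variant's HGVS-p label (or any object with a
    ``protein_change`` attribute). d6 is 1 iff at least ``agreement_min`` of
    the three categorical predictors call the variant damaging.
    """
    label = getattr(v, "protein_change", None) or str(v)
    for other in (p.variant, e.variant):
        if other and other != label:
            raise ValueError(
                f"mismatched variant labels: profile for {label!r} fed inputs for {other!r}"
            )
    return DescriptorProfile(
        d1=int(e.conserved_position),
        d2=int(e.in_functional_domain),
        d3=int(e.low_complexity_context),
        d4=int(e.in_structured_domain),
        d5=int(e.on_linear_motif),
        d6=int(predictor_damage_count(p) >= agreement_min),
        d7=int(e.prior_annotation_in_db),
        d8=int(e.literature_pathogenic),
        source_variant=label,
    )
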