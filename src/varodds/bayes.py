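"""Bayesian prior/posterior odds-ratio classifier with five pathogenicity classes.

The model combines three ingredients per variant:

* a **prior odds ratio**: 19 (95:5) for variants described as pathogenic in
  the literature, 1.25 (5:4) for variants present in dbSNP at low frequency
  with no functional data, 1 (50:50) otherwise;
* a **prediction score** in [1, 4]: one plus the number of damaging calls
  among the three categorical in-silico predictors;
* an **odd score** in [1, 5]: the count of positive structural/annotation
  descriptors (conservation, functional domain, structured domain, linear
  motif, database annotation), floored at 1.

The merged score (prediction + odd, range [2, 9]) multiplies the prior to
give the posterior OR, expressed as a percentage of the maximum merged score
(9). Classes are banded on that percentage: Pathogenic >= 90, Likely
Pathogenic >= 50, Uncertain >= 25, Likely Neutral >= 12.5, Neutral below.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .descriptors import (
    DescriptorProfile,
    EvidenceContext,
    PredictorCalls,
    build_profile,
    predictor_damage_count,
)

__all__ = [
    "BayesResult",
    "PRIOR_LITERATURE",
    "PRIOR_DBSNP",
    "PRIOR_DEFAULT",
    "assign_prior",
    "prediction_score",
    "odd_score",
    "classify",
    "classify_from_merged",
    "classify_batch",
    "results_table",
]

PRIOR_LITERATURE = 19.0  # 95:5
PRIOR_DBSNP = 1.25  # 5:4
PRIOR_DEFAULT = 1.0  # 50:50
_PRIORS = (PRIOR_LITERATURE, PRIOR_DBSNP, PRIOR_DEFAULT)

#: normalization for posterior OR%: the maximum merged score (4 + 5)
MAX_MERGED = 9

CLASS_LABELS = {
    1: ("Neutral", "N"),
    2: ("Likely Neutral", "LN"),
    3: ("Uncertain", "U"),
    4: ("Likely Pathogenic", "LP"),
    5: ("Pathogenic", "P"),
}

# (lower pct bound, class index); scanned top-down
_CLASS_BANDS = ((90.0, 5), (50.0, 4), (25.0, 3), (12.5, 2))


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BayesResult:
    """One classified variant: scores, odds and class."""

    variant: str
    prediction_score: int
    odd_score: int
    merged_score: int
    prior_or: float
    posterior_or: float
    posterior_or_pct: float
    class_index: int
    class_label: str
    class_abbrev: str
    descriptor_agreement: float | None = None


def assign_prior(e: EvidenceContext) -> float:
    """Prior odds ratio for a variant's evidence context.

    Precedence: literature > dbSNP > default.
    """
    if e.literature_pathogenic:
        return PRIOR_LITERATURE
    if e.dbsnp_low_freq_no_functional:
        return PRIOR_DBSNP
    return PRIOR_DEFAULT


def prediction_score(p: PredictorCalls) -> int:
    """1 + number of damaging categorical predictor calls, in [1, 4]."""
    return min(4, max(1, 1 + predictor_damage_count(p)))


def odd_score(d: DescriptorProfile) -> int:
    """Count of positive structural/annotation descriptors, floored at 1.

    Uses d1 (conservation), d2 (functional domain), d4 (structured domain),
    d5 (linear motif) and d7 (database annotation); the predictor descriptor
    (d6) feeds the prediction score and the literature descriptor (d8) feeds
    the prior, so neither is double-counted here.
    """
    return max(1, d.d1 + d.d2 + d.d4 + d.d5 + d.d7)


def _band(pct: float) -> int:
    for bound, idx in _CLASS_BANDS:
        if pct >= bound:
            return idx
    return 1


def classify_from_merged(
    merged: int,
    prior: float,
    *,
    prediction: int | None = None,
    odd: int | None = None,
    variant: str = "",
    descriptor_agreement: float | None = None,
) -> BayesResult:
    """Classify from a merged score directly (posterior = merged x prior)."""
    if not 2 <= merged <= 9:
        raise ValueError(f"merged score must be in [2, 9], got {merged}")
    if prior not in _PRIORS:
        raise ValueError(f"prior OR must be one of {_PRIORS}, got {prior}")
    posterior = merged * prior
    pct = _round_half_up(posterior / MAX_MERGED * 100.0)
    idx = _band(pct)
    label, abbrev = CLASS_LABELS[idx]
    return BayesResult(
        variant=variant,
        prediction_score=prediction if prediction is not None else 0,
        odd_score=odd if odd is not None else 0,
        merged_score=merged,
        prior_or=prior,
        posterior_or=posterior,
        posterior_or_pct=pct,
        class_index=idx,
        class_label=label,
        class_abbrev=abbrev,
        descriptor_agreement=descriptor_agreement,
    )


def classify(
    prediction: int,
    odd: int,
    prior: float,
    *,
    variant: str = "",
    descriptor_agreement: float | None = None,
) -> BayesResult:
    """Classify one variant from its prediction score, odd score and prior OR."""
    if not 1 <= prediction <= 4:
        raise ValueError(f"prediction score must be in [1, 4], got {prediction}")
    if not 1 <= odd <= 5:
        raise ValueError(f"odd score must be in [1, 5], got {odd}")
    return classify_from_merged(
        prediction + odd,
        prior,
        prediction=prediction,
        odd=odd,
        variant=variant,
        descriptor_agreement=descriptor_agreement,
    )


def classify_batch(
    variants: Sequence,
    predictors: Mapping[str, PredictorCalls],
    evidence: Mapping[str, EvidenceContext],
    agreement_min: int = 2,
) -> list[BayesResult]:
    """Classify a list of variants against predictor and evidence tables.

    ``variants`` holds HGVS-p labels (or objects with ``protein_change``);
    ``predictors`` and ``evidence`` are keyed by the same labels. Output
    order matches input order. A missing table row raises an error naming
    the variant.
    """
    results: list[BayesResult] = []
    for v in variants:
        label = getattr(v, "protein_change", None) or str(v)
        if label not in predictors:
            raise KeyError(f"no predictor calls for variant {label!r}")
        if label not in evidence:
            raise KeyError(f"no evidence context for variant {label!r}")
        p = predictors[label]
        e = evidence[label]
        profile = build_profile(label, p, e, agreement_min=agreement_min)
        results.append(
            classify(
                prediction_score(p),
                odd_score(profile),
                assign_prior(e),
                variant=label,
                descriptor_agreement=profile.agreement,
            )
        )
    return results


_REPORT_COLUMNS = [
    "Variant",
    "Prediction Score",
    "Odd Score",
    "Merged Score In Silico",
    "Prior OR",
    "Posterior OR",
    "Posterior OR%",
    "Meaning",
    "Class",
]


def results_table(results: Iterable[BayesResult]) -> pd.DataFrame:
    """Render results as the standard report table."""
    rows = [
        {
            "Variant": r.variant,
            "Prediction Score": r.prediction_score,
            "Odd Score": r.odd_score,
            "Merged Score In Silico": r.merged_score,
            "Prior OR": r.prior_or,
            "Posterior OR": r.posterior_or,
            "Posterior OR%": r.posterior_or_pct,
            "Meaning": r.class_abbrev,
            "Class": r.class_index,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)
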