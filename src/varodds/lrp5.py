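"""Bundled LRP5 worked example: ten rare missense variants.

Ten rare heterozygous missense LRP5 variants found in a cohort of men with
idiopathic low bone mass, with their published in-silico predictor calls and
published classifier scores. This module is the package's reference fixture
for the Bayesian classifier.

The published score table is internally inconsistent in two cells (see
``compare_with_published``): p.R1135C is printed with prediction score 2 but
a merged score of 8 alongside odd score 5 (2 + 5 != 8), and p.A1525V is
printed with prediction score 2 although none of its categorical predictor
calls is damaging. ``classify_lrp5`` always computes scores from components
and the comparison report flags, rather than silently reproduces, such cells.
The published table spells one variant p.A1515V where the genetics tables
use p.A1525V; the canonical label p.A1525V is used here.

The per-variant evidence flags are a *reconstruction*: the source analysis
reports only the aggregated odd scores, so the flags below encode a choice
of binarizations consistent with the published odd scores and the described
domain/motif/database context. They are fixture data, not measurements.
"""

from __future__ import annotations

import pandas as pd

from .bayes import (
    BayesResult,
    classify_batch,
    prediction_score,
    results_table,
)
from .descriptors import EvidenceContext, PredictorCalls

__all__ = [
    "VARIANTS",
    "published_scores",
    "predictor_calls",
    "evidence_contexts",
    "classify_lrp5",
    "compare_with_published",
]

VARIANTS = (
    "p.V99L",
    "p.G333S",
    "p.E341K",
    "p.T443M",
    "p.R1036Q",
    "p.R1135C",
    "p.R1342P",
    "p.A1525V",
    "p.A1537V",
    "p.S1585L",
)

# variant -> (prediction, odd, merged, prior, posterior, pct, meaning, class)
_PUBLISHED = {
    "p.V99L": (1, 1, 2, 1.0, 2.0, 22.22, "LN", 2),
    "p.G333S": (1, 1, 2, 1.0, 2.0, 22.22, "LN", 2),
    "p.E341K": (2, 3, 5, 1.0, 5.0, 55.56, "LP", 4),
    "p.T443M": (2, 3, 5, 1.0, 5.0, 55.56, "LP", 4),
    "p.R1036Q": (2, 5, 7, 1.25, 8.745, 97.22, "P", 5),
    "p.R1135C": (2, 5, 8, 1.25, 10.0, 111.11, "P", 5),
    "p.R1342P": (3, 3, 6, 1.0, 6.0, 66.67, "LP", 4),
    "p.A1525V": (2, 3, 5, 1.25, 6.25, 69.44, "LP", 4),
    "p.A1537V": (2, 3, 5, 1.0, 5.0, 55.56, "LP", 4),
    "p.S1585L": (4, 1, 5, 1.0, 5.0, 55.56, "LP", 4),
}

# variant -> (polyphen, sift, pmut, ddg)
_PREDICTORS = {
    "p.V99L": ("benign", "tolerated", "neutral", -0.44734934),
    "p.G333S": ("benign", "tolerated", "neutral", -1.3066037),
    "p.E341K": ("benign", "tolerated", "disease", -0.82809476),
    "p.T443M": ("probably_damaging", "tolerated", "neutral", -0.26659723),
    "p.R1036Q": ("possibly_damaging", "tolerated", "neutral", -1.171288),
    "p.R1135C": ("probably_damaging", "tolerated", "disease", -0.47636602),
    "p.R1342P": ("probably_damaging", "tolerated", "disease", -0.94002976),
    "p.A1525V": ("benign", "tolerated", "neutral", -0.35033282),
    "p.A1537V": ("benign", "not_tolerated", "neutral", -0.31014871),
    "p.S1585L": ("probably_damaging", "not_tolerated", "disease", -0.30474209),
}

# Reconstructed evidence flags (see module docstring):
# variant -> (lit, dbsnp, db_annot, func_dom, struct_dom, motif, conserved, low_cplx)
_EVIDENCE = {
    "p.V99L": (0, 0, 0, 1, 0, 0, 0, 0),
    "p.G333S": (0, 0, 0, 0, 0, 0, 0, 0),
    "p.E341K": (0, 0, 0, 1, 1, 0, 1, 0),
    "p.T443M": (0, 0, 0, 1, 1, 0, 1, 0),
    "p.R1036Q": (0, 1, 1, 1, 1, 1, 1, 0),
    "p.R1135C": (0, 1, 1, 1, 1, 1, 1, 0),
    "p.R1342P": (0, 0, 1, 0, 0, 1, 1, 1),
    "p.A1525V": (0, 1, 1, 1, 0, 1, 0, 1),
    "p.A1537V": (0, 0, 0, 1, 0, 1, 1, 1),
    "p.S1585L": (0, 0, 0, 0, 0, 1, 0, 1),
}


def published_scores() -> pd.DataFrame:
    """Published classifier table, one row per variant."""
    rows = [
        {
            "Variant": v,
            "Prediction Score": t[0],
            "Odd Score": t[1],
            "Merged Score In Silico": t[2],
            "Prior OR": t[3],
            "Posterior OR": t[4],
            "Posterior OR%": t[5],
            "Meaning": t[6],
            "Class": t[7],
        }
        for v, t in _PUBLISHED.items()
    ]
    return pd.DataFrame(rows)


def predictor_calls() -> dict[str, PredictorCalls]:
    return {
        v: PredictorCalls(polyphen=pp, sift=sf, pmut=pm, ddg=dd, variant=v)
        for v, (pp, sf, pm, dd) in _PREDICTORS.items()
    }


def evidence_contexts() -> dict[str, EvidenceContext]:
    return {
        v: EvidenceContext(
            literature_pathogenic=bool(lit),
            dbsnp_low_freq_no_functional=bool(db),
            prior_annotation_in_db=bool(ann),
            in_functional_domain=bool(fd),
            in_structured_domain=bool(sd),
            on_linear_motif=bool(mot),
            conserved_position=bool(cons),
            low_complexity_context=bool(lc),
            variant=v,
        )
        for v, (lit, db, ann, fd, sd, mot, cons, lc) in _EVIDENCE.items()
    }


def classify_lrp5(agreement_min: int = 2) -> list[BayesResult]:
    """Run the full classifier over the ten-variant fixture."""
    return classify_batch(
        list(VARIANTS), predictor_calls(), evidence_contexts(), agreement_min=agreement_min
    )


def compare_with_published() -> pd.DataFrame:
    """Recompute all scores from components and flag published discrepancies.

    Returns the recomputed report with extra columns holding the published
    prediction score / posterior OR and a ``discrepancy`` note wherever the
    published cell disagrees with its own components.
    """
    computed = results_table(classify_lrp5()).set_index("Variant")
    calls = predictor_calls()
    notes = {}
    for v, (pub_pred, pub_odd, pub_merged, _, pub_post, _, _, _) in _PUBLISHED.items():
        msgs = []
        pred = prediction_score(calls[v])
        if pred != pub_pred:
            msgs.append(f"published prediction score {pub_pred} != {pred} from predictor calls")
        if pub_pred + pub_odd != pub_merged:
            msgs.append(
                f"published merged score {pub_merged} != published prediction+odd "
                f"{pub_pred}+{pub_odd}"
            )
        if abs(pub_merged * _PUBLISHED[v][3] - pub_post) > 1e-9:
            msgs.append(
                f"published posterior {pub_post} != merged x prior "
                f"{pub_merged * _PUBLISHED[v][3]:g}"
            )
        notes[v] = "; ".join(msgs)
    out = computed.copy()
    pub = published_scores().set_index("Variant")
    out["Published Prediction Score"] = pub["Prediction Score"]
    out["Published Posterior OR"] = pub["Posterior OR"]
    out["Published Class"] = pub["Class"]
    out["discrepancy"] = pd.Series(notes)
    return out.reset_index()
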