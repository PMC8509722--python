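"""Cohort summaries and carrier vs non-carrier DXA score comparison.

Subjects carry dual-energy X-ray absorptiometry (DXA) measurements at the
lumbar spine (``_l``) and total hip (``_th``): absolute bone mineral density
(BMD, g/cm^2) and the standardized T and Z scores (SD units against
young-adult and age-matched references respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSubject",
    "NUMERIC_FIELDS",
    "group_compare",
    "summarize_cohort",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

NUMERIC_FIELDS = ("age", "bmd_l", "t_l", "z_l", "bmd_th", "t_th", "z_th")


@dataclass(frozen=True)
class CohortSubject:
    id: str
    age: float
    bmd_l: float
    t_l: float
    z_l: float
    bmd_th: float
    t_th: float
    z_th: float
    carrier: bool

    def __post_init__(self):
        for name in NUMERIC_FIELDS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.age <= 0:
            raise ValueError("age must be positive")


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test between two groups of scores.

    Pooled-variance (classic Student) by default; ``welch=True`` drops the
    equal-variance assumption. If both groups are constant with equal means
    the test is vacuous and (0.0, 1.0) is returned by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(subjects: Sequence[CohortSubject]) -> dict:
    """Mean +/- SD per numeric field, plus carrier counts.

    Returns a dict with a ``table`` DataFrame (field, mean, sd), ``n``,
    ``carrier_count``, ``carrier_pct`` (percent, 1 decimal) and a
    ``degenerate`` flag set when the cohort has a single subject (SD
    reported as 0).
    """
    if not subjects:
        raise ValueError("cohort must be non-empty")
    n = len(subjects)
    degenerate = n == 1
    rows = []
    for name in NUMERIC_FIELDS:
        vals = np.array([getattr(s, name) for s in subjects], dtype=float)
        sd = 0.0 if degenerate else float(vals.std(ddof=1))
        rows.append({"field": name, "mean": float(vals.mean()), "sd": sd})
    carriers = sum(s.carrier for s in subjects)
    return {
        "table": pd.DataFrame(rows),
        "n": n,
        "carrier_count": carriers,
        "carrier_pct": _round1(100.0 * carriers / n),
        "degenerate": degenerate,
    }


def cohort_frame(subjects: Sequence[CohortSubject]) -> pd.DataFrame:
    cols = [f.name for f in fields(CohortSubject)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in subjects])


def read_cohort_tsv(path) -> list[CohortSubject]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return [
        CohortSubject(
            id=str(r["id"]),
            age=float(r["age"]),
            bmd_l=float(r["bmd_l"]),
            t_l=float(r["t_l"]),
            z_l=float(r["z_l"]),
            bmd_th=float(r["bmd_th"]),
            t_th=float(r["t_th"]),
            z_th=float(r["z_th"]),
            carrier=bool(r["carrier"]),
        )
        for _, r in df.iterrows()
    ]


def write_cohort_tsv(subjects: Sequence[CohortSubject], path) -> None:
    cohort_frame(subjects).to_csv(path, sep="\t", index=False)
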