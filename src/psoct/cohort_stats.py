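"""Longitudinal cohort summaries and agreement statistics.

Per-visit prevalence of each lesion type, GA-area summaries over eyes with
detected GA, paired t tests for BCVA / CRT / GA-area comparisons between
visits, and the interobserver agreement statistics (Cohen's kappa with a
large-sample 95% CI, percent agreement, Spearman rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lesion_rules import EyeVisitRecord

__all__ = [
    "PrevalenceTable",
    "AgreementResult",
    "prevalence",
    "ga_area_summary",
    "paired_t",
    "cohen_kappa",
    "percent_agreement",
    "spearman_r",
]


@dataclass
class PrevalenceTable:
    """Counts and percentages of affected eyes per visit and lesion type."""

    table: pd.DataFrame  # columns: visit_month, lesion_type, n_affected, n_total, percent

    def percent(self, visit_month: int, lesion_type: str) -> float:
        t = self.table
        row = t[(t.visit_month == visit_month) & (t.lesion_type == lesion_type)]
        if row.empty:
            raise KeyError((visit_month, lesion_type))
        return float(row.percent.iloc[0])


@dataclass
class AgreementResult:
    kappa: float
    kappa_ci_low: float
    kappa_ci_high: float
    percent_agreement: float
    spearman_r: float | None = None
    degenerate: bool = False


def prevalence(records: list[EyeVisitRecord]) -> PrevalenceTable:
    """Exact per-visit, per-lesion-type counts and percentages."""
    if not records:
        raise ValueError("no records")
    rows = []
    months = sorted({r.visit_month for r in records})
    for month in months:
        visit = [r for r in records if r.visit_month == month]
        for lesion_type in EyeVisitRecord.LESION_TYPES:
            n_affected = sum(getattr(r, lesion_type) for r in visit)
            rows.append(
                {
                    "visit_month": month,
                    "lesion_type": lesion_type,
                    "n_affected": int(n_affected),
                    "n_total": len(visit),
                    "percent": 100.0 * n_affected / len(visit),
                }
            )
    return PrevalenceTable(table=pd.DataFrame(rows))


def ga_area_summary(records: list[EyeVisitRecord]) -> pd.DataFrame:
    """Per-visit mean/SD/range of GA area over eyes with detected GA.

    Eyes without detected GA are excluded, not counted as zero, matching
    the convention "of all patients in whom GA was detected".  Visits with
    no GA-positive eye appear with ``n = 0`` and NaN summaries (absence,
    not zero).
    """
    months = sorted({r.visit_month for r in records})
    rows = []
    for month in months:
        areas = np.array(
            [
                r.ga_area_mm2
                for r in records
                if r.visit_month == month and r.ga_area_mm2 > 0
            ]
        )
        if areas.size:
            rows.append(
                {
                    "visit_month": month,
                    "n": int(areas.size),
                    "mean_mm2": float(areas.mean()),
                    "sd_mm2": float(areas.std(ddof=1)) if areas.size > 1 else 0.0,
                    "min_mm2": float(areas.min()),
                    "max_mm2": float(areas.max()),
                }
            )
        else:
            rows.append(
                {
                    "visit_month": month,
                    "n": 0,
                    "mean_mm2": np.nan,
                    "sd_mm2": np.nan,
                    "min_mm2": np.nan,
                    "max_mm2": np.nan,
                }
            )
    return pd.DataFrame(rows)


def paired_t(x, y) -> tuple[float, float]:
    """Classical paired-sample t test (two-sided).

    Returns ``(t, p)`` with p from the t distribution on ``n - 1`` degrees
    of freedom.  Identical samples give ``(0, 1)``; a non-zero constant
    difference (zero variance) is a degenerate input and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = x - y
    if np.allclose(d, 0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0):
        raise ValueError(
            "zero-variance non-zero difference: paired t is undefined"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def cohen_kappa(g1, g2) -> AgreementResult:
    """Cohen's kappa on a 2x2 presence table with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e); the CI uses the Fleiss-type standard
    error with a normal approximation, clipped to [-1, 1].  When both
    graders assign a single identical category everywhere, chance agreement
    is undefined; the convention here is kappa = 1 with ``degenerate=True``.
    """
    a = np.asarray(g1, dtype=int)
    b = np.asarray(g2, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("grades must be equally long non-empty 1-D vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("grades must be 0/1")
    n = a.size
    p_o = float(np.mean(a == b))
    pa1, pb1 = a.mean(), b.mean()
    p_e = float(pa1 * pb1 + (1 - pa1) * (1 - pb1))
    pct = 100.0 * p_o
    if np.isclose(p_e, 1.0):
        kappa = 1.0 if p_o == 1.0 else 0.0
        return AgreementResult(kappa, kappa, kappa, pct, degenerate=True)
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / n) / (1 - p_e)
    lo = float(np.clip(kappa - 1.959963984540054 * se, -1, 1))
    hi = float(np.clip(kappa + 1.959963984540054 * se, -1, 1))
    return AgreementResult(float(kappa), lo, hi, pct)


def percent_agreement(g1, g2) -> float:
    """Percentage of matching grades: 100 * matches / n."""
    a = np.asarray(g1)
    b = np.asarray(g2)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("grades must be equally long and non-empty")
    return float(100.0 * np.mean(a == b))


def spearman_r(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_r requires equally long vectors, n >= 3")
    return float(stats.spearmanr(x, y).statistic)
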