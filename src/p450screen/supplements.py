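"""Cohort comparison of binary supplement intake.

Fish-oil and vitamin-D intake proportions between two cohorts are
compared with the Pearson chi-square test on the 2x2 intake table,
one degree of freedom, two-sided, *without* the Yates continuity
correction — the uncorrected statistic is what reproduces reported
screen p-values on the reference proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2_contingency

from .association import round_half_up

__all__ = ["IntakeTable", "ChiSquareResult", "pearson_chi2", "intake_proportion", "intake_report"]


@dataclass(frozen=True)
class IntakeTable:
    """Intake counts: ``x1`` of ``n1`` subjects in cohort 1 take the
    supplement, ``x2`` of ``n2`` in cohort 2."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cohort totals must be positive")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("intake counts must lie in [0, n]")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    defined: bool = True


def pearson_chi2(table: IntakeTable) -> ChiSquareResult:
    """Uncorrected Pearson chi-square on the 2x2 intake table.

    A zero margin (nobody or everybody takes the supplement in both
    cohorts) leaves the statistic undefined and is flagged rather than
    raised.
    """
    counts = [[table.x1, table.n1 - table.x1], [table.x2, table.n2 - table.x2]]
    col_margins = (table.x1 + table.x2, (table.n1 - table.x1) + (table.n2 - table.x2))
    if 0 in col_margins:
        return ChiSquareResult(float("nan"), float("nan"), defined=False)
    stat, p, _, _ = chi2_contingency(counts, correction=False)
    return ChiSquareResult(float(stat), float(p))


def intake_proportion(x: int, n: int) -> float:
    """Intake percentage 100*x/n, reported to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round_half_up(100.0 * x / n, 1)


def intake_report(
    subjects: pd.DataFrame,
    pair: tuple[str, str] = ("GUN", "GPD"),
    covariates: tuple[str, ...] = ("fish_oil", "vitamin_d"),
) -> pd.DataFrame:
    """Per-covariate intake proportions and chi-square p for one cohort
    pair, from a subject table with 0/1 supplement columns."""
    rows = []
    for covariate in covariates:
        sub = subjects[subjects["cohort"].isin(pair)]
        counts = {
            label: (int(grp[covariate].sum()), int(len(grp)))
            for label, grp in sub.groupby("cohort")
        }
        (x1, n1), (x2, n2) = counts[pair[0]], counts[pair[1]]
        res = pearson_chi2(IntakeTable(x1, n1, x2, n2))
        rows.append({
            "covariate": covariate,
            "cohort_1": pair[0], "x1": x1, "n1": n1, "pct1": intake_proportion(x1, n1),
            "cohort_2": pair[1], "x2": x2, "n2": n2, "pct2": intake_proportion(x2, n2),
            "chi2": round_half_up(res.statistic, 3) if res.defined else float("nan"),
            "p": round_half_up(res.p_value, 3) if res.defined else float("nan"),
        })
    return pd.DataFrame(rows)
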