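"""Per-variant case-control association on 2x2 carrier tables.

The statistic is the classical cross-product odds ratio with a Wald
95% confidence interval on the log scale and the matching two-sided
Wald p-value,

    OR = (a*d) / (b*c),
    SE = sqrt(1/a + 1/b + 1/c + 1/d),
    CI = exp(ln OR +/- z * SE),      z = Phi^{-1}(0.975)
    p  = 2 * (1 - Phi(|ln OR| / SE)),

where ``a``/``b`` are the counts of numerator-cohort subjects with and
without the variant and ``c``/``d`` the same for the denominator cohort.
For a single binary predictor this closed form is identical to an
unadjusted logistic regression, which is how case-control screens of
this kind are usually reported.  p-values are raw and two-sided; no
multiple-testing adjustment is applied (an optional Benjamini-Hochberg
column can be added downstream but never filters results).

Subjects with a missing genotype at a variant are excluded from that
variant's table, so the effective denominators may fluctuate from the
nominal cohort sizes variant by variant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .variant_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, VariantRecord

__all__ = [
    "CollapseMode",
    "CarrierTable",
    "AssociationResult",
    "carrier_table",
    "odds_ratio",
    "wald_interval",
    "screen",
    "results_to_frame",
    "round_half_up",
]

#: z for a central 95% interval; kept at full double precision via the
#: normal quantile rather than the textbook 1.96 so that third-decimal
#: CI bounds match standard statistical software output.
Z_95 = float(norm.ppf(0.975))


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero (the convention of SPSS-style
    report tables), as opposed to numpy's banker's rounding."""
    import decimal

    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


class CollapseMode(str, enum.Enum):
    """How diploid genotypes collapse to a binary carrier state.

    ``het_only`` counts heterozygotes as carriers, ``hom_only``
    homozygous-alternate subjects, ``any_carrier`` either.  Subjects in
    any other non-missing state count as non-carriers.
    """

    het_only = "het_only"
    hom_only = "hom_only"
    any_carrier = "any_carrier"

    def is_carrier(self, code: int) -> bool:
        if self is CollapseMode.het_only:
            return code == GT_HET
        if self is CollapseMode.hom_only:
            return code == GT_HOM_ALT
        return code in (GT_HET, GT_HOM_ALT)


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier counts: (a, b) with/without in the numerator cohort,
    (c, d) with/without in the denominator cohort, missing excluded."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier counts must be non-negative")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    def swapped(self) -> "CarrierTable":
        """The same table with numerator and denominator cohorts exchanged."""
        return CarrierTable(self.c, self.d, self.a, self.b)

    def haldane(self) -> tuple[float, float, float, float]:
        """Cells with the Haldane-Anscombe +0.5 continuity correction."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class AssociationResult:
    """One variant x cohort-pair x collapse-mode association."""

    variant_id: str
    gene: str | None
    comparison: tuple[str, str]  # numerator cohort first
    mode: CollapseMode
    table: CarrierTable
    defined: bool
    or_value: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")

    @property
    def comparison_label(self) -> str:
        return f"{self.comparison[0]}/{self.comparison[1]}"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.defined and self.p_value < alpha


def carrier_table(
    genotypes: Sequence[int] | np.ndarray,
    cohorts: Sequence[str],
    pair: tuple[str, str],
    mode: CollapseMode | str = CollapseMode.any_carrier,
) -> CarrierTable:
    """Collapse per-subject genotype codes into the 2x2 carrier table
    for one ordered cohort pair.

    ``genotypes`` and ``cohorts`` run in parallel over subjects.
    Missing calls are dropped from both the carrier and non-carrier
    counts, so row totals may be smaller than the cohort sizes.
    """
    mode = CollapseMode(mode)
    if len(genotypes) != len(cohorts):
        raise ValueError("genotypes and cohorts must align")
    counts = {pair[0]: [0, 0], pair[1]: [0, 0]}
    known = set(cohorts)
    for label in pair:
        if label not in known:
            raise ValueError(f"cohort {label!r} absent from subject assignment")
    for code, label in zip(genotypes, cohorts):
        if label not in counts or code == GT_MISSING:
            continue
        counts[label][0 if mode.is_carrier(code) else 1] += 1
    (a, b), (c, d) = counts[pair[0]], counts[pair[1]]
    return CarrierTable(a, b, c, d)


def odds_ratio(table: CarrierTable, exact: bool = False) -> float | Fraction:
    """Cross-product odds ratio (a*d)/(b*c).

    Returns NaN when a cell makes the ratio degenerate (``b*c == 0``
    gives an infinite estimate, ``a*d == 0`` a zero one); callers that
    want a finite value for such tables should use the Haldane-Anscombe
    correction via :func:`wald_interval`.  With ``exact=True`` the value
    is returned as an exact :class:`fractions.Fraction` (undefined
    tables raise ``ZeroDivisionError`` there).
    """
    if exact:
        return Fraction(table.a * table.d, table.b * table.c)
    if table.b * table.c == 0 or table.a * table.d == 0:
        return float("nan")
    return (table.a * table.d) / (table.b * table.c)


def wald_interval(
    table: CarrierTable,
    level: float = 0.95,
    haldane: bool = False,
) -> tuple[float, float, float]:
    """(ci_low, ci_high, p) for the log-odds-ratio Wald statistic.

    All four cells must be positive; a zero cell yields NaNs unless
    ``haldane`` applies the +0.5 correction to every cell.
    """
    cells = table.haldane() if haldane else (table.a, table.b, table.c, table.d)
    if min(cells) <= 0:
        return float("nan"), float("nan"), float("nan")
    a, b, c, d = (float(x) for x in cells)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if level == 0.95 else float(norm.ppf(0.5 + level / 2))
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    # two-sided normal tail: 2*(1 - Phi(x)) = erfc(x / sqrt(2))
    p = math.erfc(abs(log_or) / se / math.sqrt(2))
    return ci_low, ci_high, p


def associate(
    table: CarrierTable,
    variant_id: str = "",
    gene: str | None = None,
    pair: tuple[str, str] = ("A", "B"),
    mode: CollapseMode | str = CollapseMode.any_carrier,
    haldane: bool = False,
) -> AssociationResult:
    """Full association result for one prepared carrier table."""
    mode = CollapseMode(mode)
    cells = table.haldane() if haldane else (table.a, table.b, table.c, table.d)
    if min(cells) <= 0:
        return AssociationResult(variant_id, gene, pair, mode, table, defined=False)
    a, b, c, d = (float(x) for x in cells)
    ci_low, ci_high, p = wald_interval(table, haldane=haldane)
    return AssociationResult(
        variant_id, gene, pair, mode, table,
        defined=True,
        or_value=(a * d) / (b * c),
        ci_low=ci_low, ci_high=ci_high, p_value=p,
    )


def screen(
    entries: Iterable[tuple[VariantRecord, np.ndarray]],
    cohorts: Sequence[str] | Mapping[str, str],
    samples: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] = (("GPD", "HC"), ("GUN", "HC"), ("GPD", "GUN")),
    modes: Sequence[CollapseMode | str] = (CollapseMode.het_only, CollapseMode.hom_only),
    haldane: bool = False,
) -> list[AssociationResult]:
    """Screen every variant against every cohort pair and collapse mode.

    ``cohorts`` is either a per-sample sequence aligned with the
    genotype arrays or a mapping subject id -> cohort label (then
    ``samples`` must give the array order).  Variants with no carriers
    in either cohort of a pair yield no result for that pair/mode;
    tables that are non-degenerate but contain a zero cell are emitted
    flagged undefined (unless ``haldane``).
    """
    if isinstance(cohorts, Mapping):
        if samples is None:
            raise ValueError("samples order required with a cohort mapping")
        missing = [s for s in samples if s not in cohorts]
        if missing:
            raise ValueError(f"subjects without cohort label: {missing[:5]}")
        cohorts = [cohorts[s] for s in samples]
    cohorts = list(cohorts)
    present = set(cohorts)
    for pair in pairs:
        for label in pair:
            if label not in present:
                raise ValueError(f"cohort {label!r} has no subjects")
    modes = [CollapseMode(m) for m in modes]
    results: list[AssociationResult] = []
    for record, codes in entries:
        for pair in pairs:
            for mode in modes:
                table = carrier_table(codes, cohorts, pair, mode)
                if table.a == 0 and table.c == 0:
                    continue  # no carriers anywhere: nothing to test
                results.append(
                    associate(table, record.id, record.gene, pair, mode, haldane=haldane)
                )
    return results


def results_to_frame(results: Sequence[AssociationResult], decimals: int = 3) -> pd.DataFrame:
    """Tabulate results, with OR/CI/p rounded half-up for reporting."""
    rows = []
    for r in results:
        rows.append({
            "variant_id": r.variant_id,
            "gene": r.gene,
            "comparison": r.comparison_label,
            "mode": r.mode.value,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "OR": round_half_up(r.or_value, decimals) if r.defined else float("nan"),
            "CI_low": round_half_up(r.ci_low, decimals) if r.defined else float("nan"),
            "CI_high": round_half_up(r.ci_high, decimals) if r.defined else float("nan"),
            "p": round_half_up(r.p_value, decimals) if r.defined else float("nan"),
            "defined": r.defined,
        })
    return pd.DataFrame(rows)
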