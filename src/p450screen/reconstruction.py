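"""Inverse reconstruction of 2x2 carrier tables from published statistics.

Published per-variant screens report the odds ratio, its Wald 95%
confidence bounds and the p-value, but not the underlying counts.
Because the cohort sizes are known and carrier counts are small, the
integer 2x2 table that generated a printed (OR, CI, p) row is usually
*uniquely* recoverable by exhaustive search: enumerate carrier counts
``a`` and ``c``, allow a small number of missing genotypes to shrink
the per-variant denominators, recompute the Wald statistics forward,
and keep tables whose rounded values reproduce the printed row.

This turns a printed results table into a machine-checkable oracle:
reconstructed counts can be fed back through the forward association
code (or a synthetic cohort) and must reproduce the publication to the
printed precision.  Rows that admit no exact solution — which happens
when the original analysis dropped more genotypes than allowed, used a
different genotype coding, or rounded differently — are reported via
best-residual candidates rather than silently, so the caller can
decide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import CarrierTable, round_half_up, wald_interval

__all__ = ["ReconstructionQuery", "ReconstructionSolution", "reconstruct_counts"]


@dataclass(frozen=True)
class ReconstructionQuery:
    """One printed row to invert.

    ``n1``/``n2`` are the nominal cohort sizes; up to ``max_missing``
    subjects per cohort may be dropped to account for missing
    genotypes.  ``p_printed`` is an optional extra constraint.
    ``decimals`` is the rounding of the printed values (half-up).
    """

    or_printed: float
    ci_low_printed: float
    ci_high_printed: float
    p_printed: float | None = None
    n1: int = 317
    n2: int = 344
    max_missing: int = 2
    decimals: int = 3

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")


@dataclass(frozen=True)
class ReconstructionSolution:
    """One candidate table with its forward-recomputed statistics."""

    table: CarrierTable
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    residual: float  # max |recomputed(rounded) - printed|; 0.0 = exact
    missing1: int    # subjects dropped from cohort 1 (n1 - a - b)
    missing2: int

    @property
    def exact(self) -> bool:
        return self.residual == 0.0


def _residual(query: ReconstructionQuery, rounded: tuple[float, float, float, float]) -> float:
    o, lo, hi, p = rounded
    parts = [
        abs(o - query.or_printed),
        abs(lo - query.ci_low_printed),
        abs(hi - query.ci_high_printed),
    ]
    if query.p_printed is not None:
        parts.append(abs(p - query.p_printed))
    return max(parts)


def reconstruct_counts(
    query: ReconstructionQuery,
    carrier_max: int = 60,
    keep_candidates: int = 5,
) -> list[ReconstructionSolution]:
    """Exhaustively search integer tables reproducing a printed row.

    Carrier counts are searched up to ``carrier_max`` per cohort (the
    narrow confidence intervals of rare-variant screens imply small
    counts; raise the bound for common variants).  Exact solutions —
    every recomputed value rounds to the printed one — are all
    returned, sorted by total missingness; if none exists, the
    ``keep_candidates`` best-residual candidates are returned instead,
    sorted by (residual, missingness).  An empty list is impossible
    unless the search space itself is empty.
    """
    dec = query.decimals
    exact: list[ReconstructionSolution] = []
    candidates: list[ReconstructionSolution] = []
    for m1 in range(query.max_missing + 1):
        n1_eff = query.n1 - m1
        for m2 in range(query.max_missing + 1):
            n2_eff = query.n2 - m2
            for a in range(1, min(carrier_max, n1_eff - 1) + 1):
                b = n1_eff - a
                for c in range(1, min(carrier_max, n2_eff - 1) + 1):
                    d = n2_eff - c
                    table = CarrierTable(a, b, c, d)
                    or_value = (a * d) / (b * c)
                    ci_low, ci_high, p = wald_interval(table)
                    rounded = (
                        round_half_up(or_value, dec),
                        round_half_up(ci_low, dec),
                        round_half_up(ci_high, dec),
                        round_half_up(p, dec),
                    )
                    res = _residual(query, rounded)
                    sol = ReconstructionSolution(
                        table, or_value, ci_low, ci_high, p, res, m1, m2
                    )
                    if res == 0.0:
                        exact.append(sol)
                    elif not exact:
                        candidates.append(sol)
                        if len(candidates) > 4 * keep_candidates:
                            candidates.sort(key=_order)
                            del candidates[2 * keep_candidates:]
    if exact:
        exact.sort(key=_order)
        return exact
    candidates.sort(key=_order)
    return candidates[:keep_candidates]


def _order(sol: ReconstructionSolution) -> tuple:
    return (sol.residual, sol.missing1 + sol.missing2, sol.table.a, sol.table.c)
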