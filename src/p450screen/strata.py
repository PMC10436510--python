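"""Odds-ratio band stratification and gene-level summaries.

Significant per-variant odds ratios (raw two-sided p < 0.05) are
stratified into five bands — OR < 0.2, 0.2-0.5, 0.5 < OR < 2, 2-5 and
OR > 5 — which partition (0, inf).  The shared boundaries 0.2, 0.5,
2.0 and 5.0 belong to the closed bands 0.2-0.5 and 2.0-5.0; the
central band is open on both sides.  Gene-level band counts feed a set
of non-exclusive strength-of-association categories (no effect,
marginal, 2-5 with/without >5, >5, <0.2, >10, ...), and variants
significant in two cohort comparisons with odds ratios on the same
side of 1 are reported as concordant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import AssociationResult, CollapseMode
from .variant_io import GenePanel

__all__ = [
    "StratumBand", "GeneSummary", "ConcordantSNP",
    "band", "gene_summary", "classify_gene", "concordant_snps",
    "substrate_class", "summaries_to_frame",
]


class StratumBand(str, enum.Enum):
    LT_0_2 = "lt_0_2"
    FROM_0_2_TO_0_5 = "from_0_2_to_0_5"
    FROM_0_5_TO_2 = "from_0_5_to_2"
    FROM_2_TO_5 = "from_2_to_5"
    GT_5 = "gt_5"


BANDS = tuple(StratumBand)


def band(or_value: float) -> StratumBand:
    """Assign a defined, positive odds ratio to its stratum band."""
    if not or_value > 0 or or_value != or_value or or_value == float("inf"):
        raise ValueError(f"odds ratio must be finite and > 0, got {or_value!r}")
    if or_value < 0.2:
        return StratumBand.LT_0_2
    if or_value <= 0.5:
        return StratumBand.FROM_0_2_TO_0_5
    if or_value < 2.0:
        return StratumBand.FROM_0_5_TO_2
    if or_value <= 5.0:
        return StratumBand.FROM_2_TO_5
    return StratumBand.GT_5


@dataclass
class GeneSummary:
    """Per-gene, per-comparison band counts of significant variants."""

    gene: str
    substrate_class: str | None
    comparison: str
    band_counts: dict[StratumBand, int] = field(
        default_factory=lambda: {b: 0 for b in BANDS}
    )
    total_snps: int = 0          # all variants observed in the gene
    max_or: float | None = None  # largest significant OR, for the >10 category

    @property
    def n_significant(self) -> int:
        return sum(self.band_counts.values())


def gene_summary(
    results: Sequence[AssociationResult],
    panel: GenePanel | Sequence[str],
    comparison: str | None = None,
    alpha: float = 0.05,
) -> list[GeneSummary]:
    """Band counts of significant results per gene and comparison.

    ``panel`` supplies the gene universe (a :class:`GenePanel` or a
    plain gene list): genes without significant variants appear with
    all-zero counts.  A result carrying a gene outside the panel is a
    consistency error.  ``total_snps`` counts distinct variant ids
    observed per gene regardless of significance.
    """
    if isinstance(panel, GenePanel):
        genes = panel.genes
        classes = panel.substrate_classes
    else:
        genes, classes = list(panel), {}
    comparisons = (
        [comparison] if comparison
        else sorted({r.comparison_label for r in results})
    ) or ["GPD/GUN"]
    index: dict[tuple[str, str], GeneSummary] = {}
    observed: dict[str, set[str]] = {g: set() for g in genes}
    for comp in comparisons:
        for gene in genes:
            index[(gene, comp)] = GeneSummary(gene, classes.get(gene), comp)
    for r in results:
        if r.gene is None:
            continue
        if r.gene not in observed:
            raise ValueError(f"result gene {r.gene!r} not in panel")
        observed[r.gene].add(r.variant_id)
        if r.comparison_label not in comparisons or not r.significant(alpha):
            continue
        summary = index[(r.gene, r.comparison_label)]
        summary.band_counts[band(r.or_value)] += 1
        if summary.max_or is None or r.or_value > summary.max_or:
            summary.max_or = r.or_value
    for summary in index.values():
        summary.total_snps = len(observed[summary.gene])
    return list(index.values())


# Non-exclusive strength-of-association categories for a gene.
CATEGORY_NO_EFFECT = "no_effect"
CATEGORY_MARGINAL = "marginal"
CATEGORY_2_5_NO_GT5 = "band_2_to_5_no_gt5"
CATEGORY_2_5_AND_GT5 = "band_2_to_5_and_gt5"
CATEGORY_GT5 = "gt5"
CATEGORY_LT02 = "lt_0_2"
CATEGORY_GT5_NO_LT02 = "gt5_no_lt02"
CATEGORY_LT02_NO_GT5 = "lt02_no_gt5"
CATEGORY_GT10 = "gt10"


def classify_gene(summary: GeneSummary) -> set[str]:
    """Strength-of-association categories for one gene summary.

    Categories are membership flags and deliberately not mutually
    exclusive (a gene with both a >5 and a 2-5 variant carries several
    labels); ``no_effect`` marks genes without any significant variant.
    The >10 category needs the largest significant OR, which the
    summary carries alongside the band counts.
    """
    counts = summary.band_counts
    if summary.n_significant == 0:
        return {CATEGORY_NO_EFFECT}
    labels: set[str] = set()
    if counts[StratumBand.FROM_0_5_TO_2] > 0:
        labels.add(CATEGORY_MARGINAL)
    if counts[StratumBand.FROM_2_TO_5] > 0:
        labels.add(CATEGORY_2_5_AND_GT5 if counts[StratumBand.GT_5] > 0 else CATEGORY_2_5_NO_GT5)
    if counts[StratumBand.GT_5] > 0:
        labels.add(CATEGORY_GT5)
        if counts[StratumBand.LT_0_2] == 0:
            labels.add(CATEGORY_GT5_NO_LT02)
    if counts[StratumBand.LT_0_2] > 0:
        labels.add(CATEGORY_LT02)
        if counts[StratumBand.GT_5] == 0:
            labels.add(CATEGORY_LT02_NO_GT5)
    if summary.max_or is not None and summary.max_or > 10:
        labels.add(CATEGORY_GT10)
    return labels


@dataclass(frozen=True)
class ConcordantSNP:
    """A variant significant in two comparisons with same-side odds ratios."""

    gene: str | None
    variant_id: str
    mode: CollapseMode
    or_primary: float    # e.g. GPD/GUN
    or_secondary: float  # e.g. GPD/HC
    direction: str       # "over" | "under"


def concordant_snps(
    results_primary: Iterable[AssociationResult],
    results_secondary: Iterable[AssociationResult],
    alpha: float = 0.05,
) -> list[ConcordantSNP]:
    """Variants significant in both result sets with odds ratios on the
    same side of 1.

    Identity is (variant id, collapse mode), since the het-only and
    hom-only collapses of one rsID are distinct tests.  Direction is
    ``over`` when both ORs exceed 1 and ``under`` when both are below;
    opposite-side or boundary (OR = 1) pairs are excluded.
    """
    secondary = {
        (r.variant_id, r.mode): r for r in results_secondary if r.significant(alpha)
    }
    out: list[ConcordantSNP] = []
    for r in results_primary:
        if not r.significant(alpha):
            continue
        other = secondary.get((r.variant_id, r.mode))
        if other is None:
            continue
        if r.or_value > 1 and other.or_value > 1:
            direction = "over"
        elif 0 < r.or_value < 1 and 0 < other.or_value < 1:
            direction = "under"
        else:
            continue
        out.append(
            ConcordantSNP(r.gene, r.variant_id, r.mode, r.or_value, other.or_value, direction)
        )
    return out


def substrate_class(gene: str, panel: GenePanel | Mapping[str, str] | None = None) -> str:
    """Substrate class of a panel gene (Drugs, FattyAcids, Eicosanoids,
    Vitamins, Sterols, Unknown or RedoxPartner).

    Falls back to the packaged 60-gene mapping when no panel is given;
    unknown genes raise ``KeyError``.
    """
    if panel is None:
        from .reference import load_substrate_classes

        panel = load_substrate_classes()
    if isinstance(panel, GenePanel):
        return panel.substrate_class(gene)
    try:
        return panel[gene]
    except KeyError:
        raise KeyError(f"gene {gene!r} has no substrate class") from None


def summaries_to_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "gene": s.gene,
            "substrate_class": s.substrate_class,
            "comparison": s.comparison,
            "total_snps": s.total_snps,
        }
        row.update({b.value: s.band_counts[b] for b in BANDS})
        row["n_significant"] = s.n_significant
        rows.append(row)
    return pd.DataFrame(rows)
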