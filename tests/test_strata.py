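"""Band stratification, gene summaries, categories, concordance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p450screen.association import AssociationResult, CarrierTable, CollapseMode, associate
from p450screen.reference import load_band_counts_reference, load_concordant_reference
from p450screen.strata import (
    BANDS,
    CATEGORY_2_5_AND_GT5,
    CATEGORY_GT5,
    CATEGORY_GT5_NO_LT02,
    CATEGORY_GT10,
    CATEGORY_MARGINAL,
    CATEGORY_NO_EFFECT,
    GeneSummary,
    StratumBand,
    band,
    classify_gene,
    concordant_snps,
    gene_summary,
    substrate_class,
)


def _result(or_value, variant_id="v", gene="CYP4V2", p=0.01, comparison=("GPD", "GUN"),
            mode=CollapseMode.het_only):
    """A synthetic significant result with a prescribed odds ratio."""
    return AssociationResult(
        variant_id, gene, comparison, mode, CarrierTable(1, 1, 1, 1),
        defined=True, or_value=or_value, ci_low=or_value / 2, ci_high=or_value * 2,
        p_value=p,
    )


class TestBand:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (10.023, StratumBand.GT_5),
            (1.0, StratumBand.FROM_0_5_TO_2),
            (0.19, StratumBand.LT_0_2),
            # shared boundaries belong to the closed outer bands
            (0.2, StratumBand.FROM_0_2_TO_0_5),
            (0.5, StratumBand.FROM_0_2_TO_0_5),
            (2.0, StratumBand.FROM_2_TO_5),
            (5.0, StratumBand.FROM_2_TO_5),
            (5.001, StratumBand.GT_5),
        ],
    )
    def test_assignment(self, value, expected):
        assert band(value) is expected

    @given(st.floats(min_value=1e-9, max_value=1e9, allow_nan=False))
    @settings(deadline=None)
    def test_banding_partitions_positive_reals(self, value):
        assert band(value) in BANDS

    def test_nonpositive_rejected(self):
        for bad in (0.0, -1.0, math.nan, math.inf):
            with pytest.raises(ValueError):
                band(bad)


class TestGeneSummary:
    def test_counts_only_significant_results(self):
        results = [
            _result(10.0, "v1"),
            _result(3.0, "v2"),
            _result(1.5, "v3", p=0.2),  # not significant: observed but unbanded
        ]
        (summary,) = gene_summary(results, ["CYP4V2"])
        assert summary.n_significant == 2
        assert summary.band_counts[StratumBand.GT_5] == 1
        assert summary.band_counts[StratumBand.FROM_2_TO_5] == 1
        assert summary.total_snps == 3

    def test_genes_without_hits_get_zero_rows(self):
        summaries = gene_summary([_result(3.0)], ["CYP4V2", "CYP2J2"])
        by_gene = {s.gene: s for s in summaries}
        assert by_gene["CYP2J2"].n_significant == 0
        assert classify_gene(by_gene["CYP2J2"]) == {CATEGORY_NO_EFFECT}

    def test_gene_outside_panel_is_error(self):
        with pytest.raises(ValueError, match="not in panel"):
            gene_summary([_result(3.0, gene="NOTAGENE")], ["CYP4V2"])

    @given(st.lists(st.floats(min_value=0.01, max_value=50), max_size=20))
    @settings(deadline=None)
    def test_band_counts_sum_to_significant_count(self, ors):
        results = [_result(v, f"v{i}") for i, v in enumerate(ors)]
        (summary,) = gene_summary(results, ["CYP4V2"])
        assert summary.n_significant == len(ors)


class TestClassify:
    def test_single_strong_snp(self):
        """One OR=10.023 variant and one 2-5 variant, nothing protective."""
        results = [_result(10.023, "v1"), _result(3.0, "v2")]
        (summary,) = gene_summary(results, ["CYP4V2"])
        assert classify_gene(summary) == {
            CATEGORY_GT5, CATEGORY_GT5_NO_LT02, CATEGORY_GT10, CATEGORY_2_5_AND_GT5,
        }

    def test_marginal_only(self):
        (summary,) = gene_summary([_result(1.2)], ["CYP4V2"])
        assert classify_gene(summary) == {CATEGORY_MARGINAL}

    def test_reference_band_counts_reproduce_category_lists(self):
        """The packaged per-gene GPD/GUN band counts reproduce the
        published gene categorisation (spot checks across categories)."""
        ref = load_band_counts_reference().set_index("gene")
        def labels(gene):
            counts = dict(zip(
                BANDS,
                ref.loc[gene, ["lt_0_2", "from_0_2_to_0_5", "from_0_5_to_2",
                               "from_2_to_5", "gt_5"]],
            ))
            return classify_gene(GeneSummary(gene, None, "GPD/GUN", counts))
        assert CATEGORY_NO_EFFECT in labels("CYP2J2")
        assert CATEGORY_NO_EFFECT in labels("AdR")
        assert CATEGORY_GT5_NO_LT02 in labels("CYP4V2")
        assert CATEGORY_2_5_AND_GT5 in labels("CYP39A1")
        assert CATEGORY_GT5 not in labels("POR")
        assert CATEGORY_MARGINAL in labels("Adx")


class TestConcordance:
    def test_reported_pair_is_concordant_over(self):
        primary = [_result(1.46, "rs34115801", "CYP2C8")]
        secondary = [_result(2.1, "rs34115801", "CYP2C8", comparison=("GPD", "HC"))]
        (hit,) = concordant_snps(primary, secondary)
        assert hit.direction == "over"
        assert hit.or_primary == pytest.approx(1.46)

    def test_one_sided_significance_excluded(self):
        primary = [_result(1.46, "rs1")]
        secondary = [_result(2.1, "rs1", p=0.2, comparison=("GPD", "HC"))]
        assert concordant_snps(primary, secondary) == []

    def test_opposite_directions_excluded(self):
        primary = [_result(1.46, "rs1")]
        secondary = [_result(0.5, "rs1", comparison=("GPD", "HC"))]
        assert concordant_snps(primary, secondary) == []

    def test_identity_includes_collapse_mode(self):
        primary = [_result(1.5, "rs1", mode=CollapseMode.het_only)]
        secondary = [_result(1.5, "rs1", mode=CollapseMode.hom_only,
                             comparison=("GPD", "HC"))]
        assert concordant_snps(primary, secondary) == []

    def test_reference_table_directions(self):
        """The packaged two-comparison reference SNPs split 26 over / 49
        under, and every row is same-side by construction."""
        ref = load_concordant_reference()
        primary, secondary = [], []
        for i, row in ref.iterrows():
            primary.append(_result(row["or_gpd_gun"], f"s{i}", row["gene"]))
            secondary.append(_result(row["or_gpd_hc"], f"s{i}", row["gene"],
                                     comparison=("GPD", "HC")))
        hits = concordant_snps(primary, secondary)
        assert len(hits) == 75
        directions = [h.direction for h in hits]
        assert directions.count("under") == 49
        assert directions.count("over") == 26


class TestSubstrateClass:
    @pytest.mark.parametrize(
        "gene, expected",
        [("CYP4V2", "FattyAcids"), ("POR", "RedoxPartner"), ("CYP24A1", "Vitamins"),
         ("CYP2D6", "Drugs"), ("CYP20A1", "Unknown")],
    )
    def test_packaged_mapping(self, gene, expected):
        assert substrate_class(gene) == expected

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            substrate_class("TP53")
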