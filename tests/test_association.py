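"""Unit and property tests for the 2x2 Wald association core."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p450screen.association import (
    CarrierTable,
    CollapseMode,
    associate,
    carrier_table,
    odds_ratio,
    results_to_frame,
    round_half_up,
    screen,
    wald_interval,
)
from p450screen.variant_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, VariantRecord

# Tables with all cells positive: margins up to ~30 for the oracle sweep,
# larger for algebraic properties.
positive_tables = st.builds(
    CarrierTable,
    a=st.integers(1, 30), b=st.integers(1, 30),
    c=st.integers(1, 30), d=st.integers(1, 30),
)


@pytest.mark.parametrize(
    "table, expected_or",
    [
        (CarrierTable(9, 308, 1, 343), 10.023),
        (CarrierTable(8, 309, 1, 343), 8.880),
        (CarrierTable(5, 95, 5, 95), 1.000),
    ],
)
def test_odds_ratio_reported_values(table, expected_or):
    assert round_half_up(odds_ratio(table), 3) == pytest.approx(expected_or)


@pytest.mark.parametrize(
    "table, ci_low, ci_high, p",
    [
        (CarrierTable(9, 308, 1, 343), 1.263, 79.564, 0.029),
        (CarrierTable(11, 306, 2, 342), 1.352, 27.952, 0.019),
        (CarrierTable(8, 309, 1, 343), 1.104, 71.405, 0.040),
    ],
)
def test_wald_interval_reported_values(table, ci_low, ci_high, p):
    """Third-decimal agreement with published per-variant statistics."""
    lo, hi, pv = wald_interval(table)
    assert round_half_up(lo, 3) == pytest.approx(ci_low)
    assert round_half_up(hi, 3) == pytest.approx(ci_high)
    assert round_half_up(pv, 3) == pytest.approx(p)


def test_symmetric_table_is_null():
    table = CarrierTable(7, 40, 7, 40)
    lo, hi, p = wald_interval(table)
    assert odds_ratio(table) == 1.0
    assert p == pytest.approx(1.0)
    assert lo * hi == pytest.approx(1.0)  # CI log-symmetric about 1


def test_zero_cells_flagged_not_raised():
    assert math.isnan(odds_ratio(CarrierTable(0, 317, 1, 343)))
    assert all(math.isnan(v) for v in wald_interval(CarrierTable(3, 314, 0, 344)))
    res = associate(CarrierTable(3, 314, 0, 344))
    assert not res.defined
    # Haldane-Anscombe makes the same table finite
    res = associate(CarrierTable(3, 314, 0, 344), haldane=True)
    assert res.defined and res.or_value > 1


@given(positive_tables)
@settings(deadline=None)
def test_reciprocal_symmetry_is_exact(table):
    """Swapping cohorts inverts the OR exactly in rational arithmetic."""
    assert odds_ratio(table, exact=True) * odds_ratio(table.swapped(), exact=True) == Fraction(1)


@given(positive_tables)
@settings(deadline=None)
def test_ci_geometric_mean_is_the_or(table):
    lo, hi, _ = wald_interval(table)
    assert math.sqrt(lo * hi) == pytest.approx(odds_ratio(table), abs=1e-9)


@given(positive_tables, st.floats(0.01, 0.2))
@settings(deadline=None)
def test_wald_p_ci_consistency(table, alpha):
    """p < alpha iff 1 lies outside the (1-alpha) CI, at any alpha."""
    lo, hi, p = wald_interval(table, level=1 - alpha)
    assert (p < alpha) == (not lo <= 1 <= hi)


@given(positive_tables)
@settings(deadline=None)
def test_wald_matches_independent_closed_form(table):
    """Cross-check against statsmodels' 2x2 log-odds machinery."""
    from statsmodels.stats.contingency_tables import Table2x2

    oracle = Table2x2(
        np.array([[table.a, table.b], [table.c, table.d]]), shift_zeros=False
    )
    lo, hi, p = wald_interval(table)
    assert odds_ratio(table) == pytest.approx(oracle.oddsratio, rel=1e-12)
    olo, ohi = oracle.oddsratio_confint(0.05)
    assert lo == pytest.approx(olo, rel=1e-9)
    assert hi == pytest.approx(ohi, rel=1e-9)
    assert p == pytest.approx(oracle.oddsratio_pvalue(), abs=1e-12)


class TestCarrierTable:
    cohorts = ["GPD"] * 4 + ["GUN"] * 4 + ["HC"] * 2

    def test_collapse_modes(self):
        codes = [GT_HET, GT_HET, GT_HOM_ALT, GT_HOM_REF,
                 GT_HET, GT_HOM_REF, GT_HOM_REF, GT_HOM_REF,
                 GT_HET, GT_HOM_REF]
        het = carrier_table(codes, self.cohorts, ("GPD", "GUN"), CollapseMode.het_only)
        assert (het.a, het.b, het.c, het.d) == (2, 2, 1, 3)
        hom = carrier_table(codes, self.cohorts, ("GPD", "GUN"), CollapseMode.hom_only)
        assert (hom.a, hom.b, hom.c, hom.d) == (1, 3, 0, 4)
        any_ = carrier_table(codes, self.cohorts, ("GPD", "GUN"), CollapseMode.any_carrier)
        assert (any_.a, any_.b, any_.c, any_.d) == (3, 1, 1, 3)

    def test_missing_excluded_from_both_counts(self):
        codes = [GT_HET, GT_MISSING, GT_HOM_REF, GT_HOM_REF,
                 GT_HOM_REF, GT_HOM_REF, GT_MISSING, GT_HET,
                 GT_HOM_REF, GT_HOM_REF]
        t = carrier_table(codes, self.cohorts, ("GPD", "GUN"), CollapseMode.any_carrier)
        assert t.n1 == 3 and t.n2 == 3

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            carrier_table([GT_HET] * 10, self.cohorts, ("GPD", "IPD"))


class TestScreen:
    def _entries(self):
        rec = VariantRecord("1", 100, "C", "T", id="rs1", gene="CYP4V2")
        codes = np.array([GT_HET, GT_HOM_REF, GT_HOM_REF, GT_HET, GT_HOM_REF, GT_HOM_REF],
                         dtype=np.int8)
        return [(rec, codes)]

    cohorts = ["GPD", "GPD", "GPD", "GUN", "GUN", "GUN"]

    def test_reciprocal_pair_inverts_or(self):
        fwd = screen(self._entries(), self.cohorts, pairs=[("GPD", "GUN")],
                     modes=["het_only"])[0]
        rev = screen(self._entries(), self.cohorts, pairs=[("GUN", "GPD")],
                     modes=["het_only"])[0]
        assert fwd.or_value * rev.or_value == pytest.approx(1.0)

    def test_no_carriers_emits_nothing(self):
        rec = VariantRecord("1", 100, "C", "T", id="rs1")
        codes = np.zeros(6, dtype=np.int8)
        assert screen([(rec, codes)], self.cohorts, pairs=[("GPD", "GUN")]) == []

    def test_empty_cohort_is_config_error(self):
        with pytest.raises(ValueError, match="no subjects"):
            screen(self._entries(), self.cohorts, pairs=[("GPD", "HC")])

    def test_frame_rounding(self):
        frame = results_to_frame(
            [associate(CarrierTable(9, 308, 1, 343), "rs138504382", "CYP4V2",
                       ("GPD", "GUN"), "het_only")]
        )
        row = frame.iloc[0]
        assert (row["OR"], row["CI_low"], row["CI_high"], row["p"]) == (
            10.023, 1.263, 79.564, 0.029
        )
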