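"""Micro-costing: inflation chain-linking, annuitization, pricing, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dcea import costing
from t2dcea.costing import (
    ActivityRecord,
    PriceIndexSeries,
    UnitCost,
    UnitCostTable,
    aggregate_costs,
    annuitize,
    annuity_factor,
    inflate_cost,
    per_patient_cost,
    price_activities,
    round_half_up,
)


@pytest.fixture
def two_regime_indices():
    return PriceIndexSeries(
        hchs={"2013/14": 100.0, "2014/15": 101.0},
        nhscii={"2014/15": 100.0, "2018/19": 100.0, "2019/20": 104.0},
    )


class TestInflation:
    def test_identity_year(self, two_regime_indices):
        assert inflate_cost(100.0, "2019/20", "2019/20", two_regime_indices) == 100.0

    def test_direct_ratio_within_regime(self):
        indices = PriceIndexSeries(
            hchs={"2014/15": 100.0},
            nhscii={"2014/15": 100.0, "2018/19": 100.0, "2019/20": 102.0},
        )
        assert inflate_cost(100.0, "2018/19", "2019/20", indices) == pytest.approx(102.0)

    def test_chain_link_across_regimes(self, two_regime_indices):
        # 100 x (101/100) across HCHS, then x (104/100) across NHSCII
        assert inflate_cost(100.0, "2013/14", "2019/20", two_regime_indices) == pytest.approx(
            105.04
        )

    def test_missing_year_names_the_year(self, two_regime_indices):
        with pytest.raises(KeyError, match="2016/17"):
            inflate_cost(100.0, "2013/14", "2016/17", two_regime_indices)

    @given(amount=st.floats(0.01, 1e6), direction=st.sampled_from([("2013/14", "2019/20"), ("2018/19", "2014/15")]))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, amount, direction):
        indices = PriceIndexSeries(
            hchs={"2013/14": 100.0, "2014/15": 101.0},
            nhscii={"2014/15": 100.0, "2018/19": 100.0, "2019/20": 104.0},
        )
        a, b = direction
        there = inflate_cost(amount, a, b, indices)
        back = inflate_cost(there, b, a, indices)
        assert back == pytest.approx(amount, abs=1e-9 * max(1.0, amount))


class TestAnnuitize:
    def test_zero_rate_splits_evenly(self):
        assert annuitize(1000.0, 5, 0.0, "advance") == pytest.approx(200.0)

    def test_annuity_due_closed_form(self):
        # factor (1 - 1.035^-5)/0.035 x 1.035 = 4.67308
        assert annuitize(1000.0, 5, 0.035, "advance") == pytest.approx(213.99, abs=0.005)

    def test_single_year_arrears(self):
        assert annuitize(1000.0, 1, 0.035, "arrears") == pytest.approx(1035.0)

    @pytest.mark.parametrize("rate", [0.0, 0.035, 0.1])
    @pytest.mark.parametrize("timing", ["advance", "arrears"])
    def test_annuity_factor_recovers_one_off(self, rate, timing):
        annual = annuitize(1234.5, 7, rate, timing)
        assert annual * annuity_factor(7, rate, timing) == pytest.approx(1234.5)

    def test_rejects_zero_years(self):
        with pytest.raises(ValueError):
            annuitize(1000.0, 0, 0.035)


class TestActivityRecord:
    def test_requires_exactly_one_population(self):
        with pytest.raises(ValueError):
            ActivityRecord("s", "waitlist", "travel", "2019/20")
        with pytest.raises(ValueError):
            ActivityRecord(
                "s", "waitlist", "travel", "2019/20",
                staff_role="x", minutes=10.0, expense_gbp=5.0,
            )

    def test_provider_staff_only_in_provider_group(self):
        with pytest.raises(ValueError):
            ActivityRecord(
                "s", "waitlist", "provider_staff", "2019/20", staff_role="x", minutes=10.0
            )

    def test_ledger_round_trip(self, tmp_path):
        records = [
            ActivityRecord("a", "waitlist", "travel", "2019/20", expense_gbp=12.5),
            ActivityRecord("b", "immediate", "practice_staff", "2018/19",
                           staff_role="nurse", minutes=90.0),
        ]
        path = tmp_path / "ledger.csv"
        costing.write_ledger(records, path)
        assert costing.read_ledger(path) == records


class TestPricing:
    def test_one_hour_same_year(self, two_regime_indices):
        rec = ActivityRecord("s", "waitlist", "embedder_direct", "2019/20",
                             staff_role="embedder", minutes=60.0)
        table = UnitCostTable({"embedder": UnitCost(30.0, "2019/20")})
        priced = price_activities([rec], table, two_regime_indices, "2019/20")
        assert priced["cost_gbp"].iloc[0] == pytest.approx(30.0)

    def test_fractional_hours(self, two_regime_indices):
        rec = ActivityRecord("s", "waitlist", "embedder_direct", "2019/20",
                             staff_role="embedder", minutes=90.0)
        table = UnitCostTable({"embedder": UnitCost(40.0, "2019/20")})
        priced = price_activities([rec], table, two_regime_indices, "2019/20")
        assert priced["cost_gbp"].iloc[0] == pytest.approx(60.0)

    def test_expense_inflated(self):
        indices = PriceIndexSeries(
            hchs={"2014/15": 100.0},
            nhscii={"2014/15": 100.0, "2018/19": 100.0, "2019/20": 102.0},
        )
        rec = ActivityRecord("s", "immediate", "travel", "2018/19", expense_gbp=500.0)
        priced = price_activities([rec], UnitCostTable({}), indices, "2019/20")
        assert priced["cost_gbp"].iloc[0] == pytest.approx(510.0)

    def test_toolkit_annuitized_before_aggregation(self, two_regime_indices):
        one_off = 1000.0
        rec = ActivityRecord("s", "waitlist", "toolkit", "2019/20", expense_gbp=one_off)
        priced = price_activities([rec], UnitCostTable({}), two_regime_indices, "2019/20")
        assert priced["cost_gbp"].iloc[0] == pytest.approx(one_off / annuity_factor(5, 0.035))

    def test_unknown_role_lists_it(self, two_regime_indices):
        rec = ActivityRecord("s", "waitlist", "embedder_direct", "2019/20",
                             staff_role="mystery", minutes=60.0)
        with pytest.raises(KeyError, match="mystery"):
            price_activities([rec], UnitCostTable({}), two_regime_indices, "2019/20")


class TestAggregation:
    def test_single_record_is_its_own_total(self, two_regime_indices):
        rec = ActivityRecord("s", "waitlist", "travel", "2019/20", expense_gbp=10.0)
        summary = aggregate_costs(
            price_activities([rec], UnitCostTable({}), two_regime_indices, "2019/20")
        )
        assert summary.grand_total == pytest.approx(10.0)
        assert summary.cell_percentages().loc["travel", "waitlist"] == pytest.approx(100.0)

    def test_conservation(self, fixture_summary, indices, unit_costs):
        from t2dcea.synthdata import fixture_ledger

        priced = price_activities(fixture_ledger(), unit_costs, indices, "2019/20")
        assert fixture_summary.grand_total == pytest.approx(priced["cost_gbp"].sum(), abs=0.005)
        assert fixture_summary.grand_total == pytest.approx(
            fixture_summary.row_totals.sum(), abs=1e-9
        )
        assert fixture_summary.grand_total == pytest.approx(
            fixture_summary.column_totals.sum(), abs=1e-9
        )

    def test_row_percentages_sum_to_100(self, fixture_summary):
        pct = fixture_summary.cell_percentages()
        sums = pct.sum(axis=1, skipna=True)
        assert np.allclose(sums, 100.0)

    def test_doubling_records_doubles_cells(self, indices, unit_costs):
        from t2dcea.synthdata import fixture_ledger

        once = aggregate_costs(
            price_activities(fixture_ledger(), unit_costs, indices, "2019/20")
        )
        twice = aggregate_costs(
            price_activities(fixture_ledger() * 2, unit_costs, indices, "2019/20")
        )
        assert np.allclose(twice.table.to_numpy(), 2.0 * once.table.to_numpy())


class TestPerPatientCost:
    def test_identity_scaling(self):
        assert per_patient_cost(204.0, 204.0, 204) == pytest.approx(1.0)

    def test_followup_adjustment(self):
        # waitlist-style group: shorter follow-up scaled up to 204 days
        value = per_patient_cost(5490.0, 134.0, 16_709)
        assert value == pytest.approx(0.50, abs=0.005)

    def test_zero_cost(self):
        assert per_patient_cost(0.0, 10.0, 5) == 0.0

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_in_cost(self, scale):
        base = per_patient_cost(1000.0, 150.0, 250)
        assert per_patient_cost(scale * 1000.0, 150.0, 250) == pytest.approx(scale * base)

    def test_inverse_in_patient_count(self):
        assert per_patient_cost(1000.0, 150.0, 500) == pytest.approx(
            per_patient_cost(1000.0, 150.0, 250) / 2.0
        )

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            per_patient_cost(100.0, 0.0, 10)
        with pytest.raises(ValueError):
            per_patient_cost(100.0, 100.0, 0)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.5) == 1.0
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(-0.5) == -1.0
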