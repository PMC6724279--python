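"""Costing rules: published-table arithmetic and per-cycle direct costs."""

import pytest
from hypothesis import given, strategies as st

from t1dcea.costing import (
    CostTable,
    CycleSnapshot,
    DisabilityDurations,
    SalaryTable,
    annual_direct_cost,
    indirect_cost,
    inflate_drg,
    insulin_annual_cost,
    subsequent_year_cost,
    therapy_annual_cost,
    to_usd,
    weighted_cost,
)


@pytest.fixture(scope="module")
def table():
    return CostTable.default()


class TestSubsequentYearRule:
    #: the five cardiovascular maintenance rows: event-year cost -> printed
    #: subsequent-year cost, each exactly event/9 to the centavo
    ROWS = [
        (267_057.59, 29_673.07),  # myocardial infarction
        (108_136.66, 12_015.18),  # angina
        (155_593.67, 17_288.19),  # congestive heart failure
        (41_540.56, 4_615.62),  # stroke
        (83_605.69, 9_289.52),  # peripheral vascular disease
    ]

    @pytest.mark.parametrize("event,subsequent", ROWS)
    def test_reproduces_all_printed_rows_to_the_centavo(self, event, subsequent):
        assert subsequent_year_cost(event) == subsequent

    def test_rows_match_the_shipped_table(self, table):
        for name in ("myocardial_infarction", "angina", "congestive_heart_failure",
                     "stroke", "peripheral_vascular_disease"):
            d = table.events[name]
            assert subsequent_year_cost(d["event_year"]) == d["subsequent_year"]

    def test_zero_and_negative(self):
        assert subsequent_year_cost(0.0) == 0.0
        with pytest.raises(ValueError):
            subsequent_year_cost(-1.0)


class TestCurrencyAndInflation:
    def test_therapy_costs_convert_to_printed_usd(self, table):
        assert to_usd(table.therapy["csii_annual"]) == 2_912.89
        assert to_usd(table.therapy["mdi_annual"]) == 1_244.42

    def test_zero(self):
        assert to_usd(0.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=1e7))
    def test_round_trip_within_rounding(self, x):
        assert to_usd(x) * 18.390 == pytest.approx(x, abs=18.390 / 100)

    def test_drg_inflation_single_application(self):
        assert inflate_drg(100.0) == pytest.approx(108.65)
        assert inflate_drg(0.0) == 0.0
        assert inflate_drg(123.45) / 1.0865 == pytest.approx(123.45)


class TestInsulin:
    def test_published_footnote_chain(self):
        r = insulin_annual_cost(65.45, 0.1, 2.12)
        assert r["daily_iu"] == pytest.approx(6.545)
        assert r["annual_iu"] == pytest.approx(2_388.925)
        assert r["annual_mxn"] == pytest.approx(2_388.925 * 2.12)

    def test_zero_dose_zero_cost(self):
        assert insulin_annual_cost(65.45, 0.0, 2.12)["annual_mxn"] == 0.0


class TestTherapy:
    def test_arm_costs(self, table):
        assert therapy_annual_cost("CSII", table) == 53_568.00
        assert therapy_annual_cost("MDI", table) == 22_884.97
        with pytest.raises(ValueError):
            therapy_annual_cost("PUMP", table)

    def test_four_year_amortization_arithmetic(self, table):
        # 20 years of annualized pump cost equals 5 pump purchases
        pump_price = 4 * table.therapy["csii_annual"]  # whole-bundle 4-year outlay
        assert 20 * table.therapy["csii_annual"] == pytest.approx(5 * pump_price)


class TestWeightedCost:
    def test_simple_average(self):
        assert weighted_cost([(100, 0.5), (200, 0.5)]) == 150.0
        assert weighted_cost([(321.5, 1.0)]) == 321.5

    def test_dialysis_mix_is_bounded_by_components(self):
        lo, hi = 250_000.0, 360_000.0
        w = weighted_cost([(lo, 0.54), (hi, 0.46)])
        assert lo < w < hi

    def test_bad_shares_rejected(self):
        with pytest.raises(ValueError):
            weighted_cost([(100, 0.5), (200, 0.4)])
        with pytest.raises(ValueError):
            weighted_cost([(100, -0.5), (200, 1.5)])


class TestAnnualDirectCost:
    def test_therapy_only_for_clean_mdi_patient(self, table):
        snap = CycleSnapshot(arm="MDI", screening=False)
        cost = annual_direct_cost(snap, table=table)
        assert cost["total"] == 22_884.97
        assert cost["treatment"] == 22_884.97

    def test_severe_hypo_adds_printed_event_cost(self, table):
        base = annual_direct_cost(CycleSnapshot(arm="MDI", screening=False), table=table)
        hypo = annual_direct_cost(
            CycleSnapshot(arm="MDI", screening=False, acute_events={"severe_hypo": 1}),
            table=table,
        )
        assert hypo["total"] - base["total"] == pytest.approx(37_000.53)
        assert hypo["hypoglycemia"] == pytest.approx(37_000.53)

    def test_categories_sum_to_total_and_are_monotone(self, table):
        snap = CycleSnapshot(
            arm="CSII",
            incident_states={"myocardial_infarction"},
            prevalent_states={"neuropathy", "hemodialysis"},
            acute_events={"severe_hypo": 2, "minor_hypo": 1},
            medications={"statins", "ace_inhibitors"},
            has_depression=True,
        )
        cost = annual_direct_cost(snap, table=table)
        cats = {k: v for k, v in cost.items() if k != "total"}
        assert sum(cats.values()) == pytest.approx(cost["total"])
        more = annual_direct_cost(
            CycleSnapshot(
                arm="CSII", incident_states=snap.incident_states,
                prevalent_states=snap.prevalent_states,
                acute_events={"severe_hypo": 3, "minor_hypo": 1},
                medications=snap.medications, has_depression=True,
            ),
            table=table,
        )
        assert more["total"] > cost["total"]

    def test_fatal_stroke_costed_at_death_drg(self, table):
        fatal = annual_direct_cost(
            CycleSnapshot(arm="MDI", incident_states={"stroke"},
                          fatal_complication="stroke", screening=False),
            table=table,
        )
        nonfatal = annual_direct_cost(
            CycleSnapshot(arm="MDI", incident_states={"stroke"}, screening=False),
            table=table,
        )
        assert fatal["cardiovascular"] == pytest.approx(41_104.86)
        assert nonfatal["cardiovascular"] == pytest.approx(41_540.56)

    def test_unknown_items_raise(self, table):
        with pytest.raises(KeyError):
            annual_direct_cost(
                CycleSnapshot(arm="MDI", incident_states={"gout"}), table=table
            )
        with pytest.raises(KeyError):
            annual_direct_cost(
                CycleSnapshot(arm="MDI", acute_events={"sneeze": 1}), table=table
            )


class TestIndirectCost:
    def test_outside_working_age_is_zero(self):
        assert indirect_cost(65.0, "male", 100.0) == 0.0
        assert indirect_cost(17.0, "male", 100.0) == 0.0
        assert indirect_cost(60.0, "female", 10.0) == 0.0  # retirement at 60

    def test_published_salaries(self):
        assert indirect_cost(40.0, "male", 10.0) == pytest.approx(3_337.60)
        assert indirect_cost(40.0, "female", 255.0) == pytest.approx(74_684.40)

    def test_days_capped_at_annual_workdays(self):
        assert indirect_cost(40.0, "female", 400.0) == pytest.approx(74_684.40)

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            indirect_cost(40.0, "male", -1.0)


def test_disability_defaults_are_neutral():
    d = DisabilityDurations()
    assert d.get("myocardial_infarction") == 0.0
    with pytest.raises(ValueError):
        DisabilityDurations(days={"stroke": -2})


def test_salary_table_invariants():
    with pytest.raises(ValueError):
        SalaryTable(retirement_age=18, first_income_age=60)
    assert SalaryTable().daily_salary("male") == 333.76
    assert SalaryTable().daily_salary("female") == 292.88


def test_cost_table_scaling_for_psa(table):
    scaled = table.scaled({"csii_annual": 1.1, "myocardial_infarction": 2.0})
    assert scaled.therapy["csii_annual"] == pytest.approx(53_568.0 * 1.1)
    assert scaled.events["myocardial_infarction"]["event_year"] == pytest.approx(
        2 * 267_057.59
    )
    assert scaled.therapy["mdi_annual"] == table.therapy["mdi_annual"]
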