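"""Costing engine: scaling, valuation, transition rules, aggregation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carebench import (
    RunConfig,
    apply_transition_rules,
    default_price_table,
    hospital_nights,
    scale_to_quarter,
    six_month_cost,
    value_wave,
)
from carebench.costing import (
    COMMUNITY_CATEGORIES,
    CostingError,
    aggregate,
    complete_six_month,
    wave_cost_table,
)
from carebench.data_io import CATEGORIES

from conftest import make_items, make_record


class TestScaleToQuarter:
    @pytest.mark.parametrize(
        "quantity,recall,expected",
        [
            (0.0, 90, 0.0),
            (0.0, 3, 0.0),
            (7.0, 7, 91.0),           # 7 hours over a 7-day recall -> 91 per quarter
            (2.0, 90, 2.0 * 91 / 90),  # 2 events over 90 days -> 2.0222... per quarter
            (3.0, 3, 91.0),
        ],
    )
    def test_quoted_formula(self, quantity, recall, expected):
        assert scale_to_quarter(quantity, recall) == pytest.approx(expected)

    def test_missing_propagates_as_nan(self):
        assert math.isnan(scale_to_quarter(None, 90))

    def test_negative_rejected(self):
        with pytest.raises(CostingError):
            scale_to_quarter(-1.0, 90)


class TestHospitalNights:
    def test_recorded_days_country_uses_registered_days(self):
        nights = hospital_nights(
            events=3, country="BE", recorded_days=12.0,
            los_table={"NL": 6.1}, recorded_days_country="BE",
        )
        assert nights == 12.0

    def test_other_countries_multiply_events_by_mean_los(self):
        nights = hospital_nights(2, "NL", None, {"NL": 8.0}, "BE")
        assert nights == 16.0

    def test_zero_events_zero_nights(self):
        assert hospital_nights(0, "NL", None, {"NL": 8.0}, "BE") == 0.0

    def test_missing_los_entry_errors(self):
        with pytest.raises(CostingError, match="length-of-stay"):
            hospital_nights(1, "FR", None, {"NL": 8.0}, "BE")

    def test_recorded_days_outside_recorded_country_errors(self):
        with pytest.raises(CostingError, match="recorded-days country"):
            hospital_nights(1, "NL", 5.0, {"NL": 8.0}, "BE")


class TestValueWave:
    def test_all_zero_quantities_give_all_zero_categories(self, prices):
        costs = value_wave(make_record(), prices)
        assert all(costs[cat] == 0.0 for cat in CATEGORIES)

    def test_home_care_linearity(self, prices):
        # 91 hours of home care per quarter at unit cost u -> 91u
        rec = make_record(items=make_items(home_care_min=7 * 60.0))
        costs = value_wave(rec, prices)
        assert costs["home_care"] == pytest.approx(
            91.0 * prices.unit_costs["home_care_hour"]
        )

    def test_mixed_fixture_matches_item_by_item_hand_computation(self, prices):
        quantities = dict(
            hosp_events=1.0,
            er_visits=2.0,
            physician_visits=3.0,
            home_care_min=420.0,
            informal_care_min=180.0,
        )
        rec = make_record(items=make_items(**quantities), country="NL")
        costs = value_wave(rec, prices)
        # Brute-force oracle: scale each item, price it, accumulate.
        u = prices.unit_costs
        hospital = (1.0 * prices.hospital_los["NL"]) * 91 / 90 * u["hospital_night"]
        visits = 2.0 * 91 / 90 * u["er_visit"] + 3.0 * 91 / 90 * u["physician_visit"]
        home = 420.0 * 91 / 7 / 60 * u["home_care_hour"]
        informal = 180.0 * 91 / 3 / 60 * prices.informal_care_wage
        assert costs["hospital"] == pytest.approx(hospital)
        assert costs["visits"] == pytest.approx(visits)
        assert costs["home_care"] == pytest.approx(home)
        assert costs["informal_care"] == pytest.approx(informal)
        assert costs["institutional"] == 0.0

    def test_missing_item_makes_category_nan_only(self, prices):
        rec = make_record(items=make_items(er_visits=None, home_care_min=60.0))
        costs = value_wave(rec, prices)
        assert math.isnan(costs["visits"])
        assert costs["home_care"] > 0


def day_by_day_accrual(c1, c2, status, per_diem, quarter_days=91):
    """Independent oracle: accrue the 182-day window one day at a time.

    In-care clients accrue the average of the two assessments' rates over the
    first quarter and the month-6 rate over the second; deceased and
    institutionalized clients accrue the baseline rate before the midpoint
    and zero / the facility per-diem after it.
    """
    total = {cat: 0.0 for cat in CATEGORIES}
    for day in range(2 * quarter_days):
        before = day < quarter_days
        for cat in COMMUNITY_CATEGORIES:
            if status == "in_care":
                rate = (
                    (c1[cat] + c2[cat]) / (2 * quarter_days)
                    if before
                    else c2[cat] / quarter_days
                )
            else:
                rate = c1[cat] / quarter_days if before else 0.0
            total[cat] += rate
        if status == "institutionalized" and not before:
            total["institutional"] += per_diem
    return total


class TestTransitionRules:
    def test_in_care_is_identity(self):
        costs = {cat: 100.0 for cat in CATEGORIES}
        assert apply_transition_rules(costs, "in_care", None) == costs

    def test_deceased_zero_cost_after_midpoint(self):
        carry = {cat: 1000.0 for cat in COMMUNITY_CATEGORIES}
        adjusted = apply_transition_rules(carry, "deceased", None)
        # six-month total must equal exactly one baseline quarter
        for cat in COMMUNITY_CATEGORIES:
            assert six_month_cost(1000.0, adjusted[cat]) == pytest.approx(1000.0)
        assert adjusted["institutional"] == 0.0

    def test_institutionalized_accrues_per_diem_after_midpoint(self):
        carry = {cat: 0.0 for cat in COMMUNITY_CATEGORIES}
        adjusted = apply_transition_rules(carry, "institutionalized", 170.0)
        assert six_month_cost(0.0, adjusted["institutional"]) == pytest.approx(
            170.0 * 91
        )

    def test_institutionalized_without_per_diem_errors(self):
        with pytest.raises(CostingError, match="per-diem"):
            apply_transition_rules({}, "institutionalized", None)

    def test_discharged_and_lost_stay_missing(self):
        assert apply_transition_rules({}, "discharged", None) is None
        assert apply_transition_rules({}, "lost", None) is None

    @pytest.mark.parametrize("status", ["in_care", "deceased", "institutionalized"])
    def test_matches_day_by_day_accrual_oracle(self, status, rng):
        """Randomized 182-day accrual check across all status cases."""
        for _ in range(200):
            c1 = {cat: float(rng.gamma(1.0, 500.0)) for cat in COMMUNITY_CATEGORIES}
            c1["institutional"] = 0.0
            c2 = {cat: float(rng.gamma(1.0, 500.0)) for cat in COMMUNITY_CATEGORIES}
            c2["institutional"] = 0.0
            per_diem = float(rng.uniform(50, 400))
            wave2 = c2 if status == "in_care" else c1
            adjusted = apply_transition_rules(wave2, status, per_diem)
            oracle = day_by_day_accrual(c1, c2, status, per_diem)
            for cat in CATEGORIES:
                got = six_month_cost(c1.get(cat, 0.0), adjusted[cat])
                assert got == pytest.approx(oracle[cat], rel=1e-9, abs=1e-6)


class TestSixMonthCost:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [(0.0, 0.0, 0.0), (700.0, 700.0, 1400.0), (1000.0, 2000.0, 3500.0)],
    )
    def test_quoted_weights(self, c1, c2, expected):
        assert six_month_cost(c1, c2) == expected

    @given(c=st.floats(0, 1e6, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_equal_quarters_double(self, c):
        assert six_month_cost(c, c) == pytest.approx(2 * c)


class TestCohortPipeline:
    def _completed(self, small_cohort, prices, config):
        # Complete-case subset: keep clients whose month-6 costs are either
        # fully observed or determined by the transition rule.
        records, _, _ = small_cohort
        wave = wave_cost_table(records, prices, config)
        observed_m6 = wave[[f"{c}_m6" for c in CATEGORIES]].notna().all(axis=1)
        rule = wave["status"].isin(["deceased", "institutionalized"])
        keep = (observed_m6 | rule).to_numpy()
        return complete_six_month(wave[keep].reset_index(drop=True), prices, config)

    def test_conservation_identities(self, small_cohort, prices, config):
        completed = self._completed(small_cohort, prices, config)
        healthcare = sum(
            completed[f"{c}_6m"] for c in CATEGORIES if c != "informal_care"
        )
        societal = healthcare + completed["informal_care_6m"]
        assert (completed["total_healthcare_6m"] == healthcare).all()
        assert (completed["total_societal_6m"] == societal).all()
        assert (
            completed["total_healthcare_6m"] <= completed["total_societal_6m"]
        ).all()

    def test_remaining_missingness_is_an_error(self, small_cohort, prices, config):
        records, _, _ = small_cohort
        wave = wave_cost_table(records, prices, config)
        assert wave.filter(regex="_m6$").isna().to_numpy().any()
        with pytest.raises(CostingError, match="impute"):
            complete_six_month(wave, prices, config)

    def test_price_homogeneity(self, small_cohort, config):
        """Scaling every unit cost by k scales every cost output by exactly k."""
        records, _, _ = small_cohort
        base = default_price_table()
        k = 2.5
        completed_1 = self._completed(small_cohort, base, config)
        completed_k = self._completed(small_cohort, base.scaled(k), config)
        for col in [f"{c}_6m" for c in CATEGORIES] + [
            "total_societal_6m",
            "total_healthcare_6m",
        ]:
            np.testing.assert_allclose(
                completed_k[col], k * completed_1[col], rtol=1e-12
            )


class TestAggregate:
    def test_single_client_group_mean_is_that_client(self, small_cohort, prices, config):
        completed = TestCohortPipeline()._completed(small_cohort, prices, config)
        one = completed.head(1).assign(model="CMX")
        table = aggregate(one, "societal")
        assert table.loc[0, "total_mean"] == one["total_societal_6m"].iloc[0]

    def test_healthcare_total_is_societal_minus_informal(
        self, small_cohort, prices, config
    ):
        completed = TestCohortPipeline()._completed(small_cohort, prices, config)
        completed = completed.assign(model="CMX")
        societal = aggregate(completed, "societal")
        healthcare = aggregate(completed, "healthcare")
        assert healthcare.loc[0, "total_mean"] == pytest.approx(
            societal.loc[0, "total_mean"] - societal.loc[0, "informal_care_mean"]
        )
        assert "informal_care_mean" not in healthcare.columns

    def test_constructed_ratio(self, prices, config):
        frame = {f"{c}_6m": [0.0, 0.0] for c in CATEGORIES}
        frame["home_care_6m"] = [100.0, 300.0]
        frame["informal_care_6m"] = [300.0, 900.0]
        import pandas as pd

        completed = pd.DataFrame(frame)
        completed["total_societal_6m"] = sum(
            completed[f"{c}_6m"] for c in CATEGORIES
        )
        completed["total_healthcare_6m"] = (
            completed["total_societal_6m"] - completed["informal_care_6m"]
        )
        completed["model"] = "CM1"
        table = aggregate(completed, "societal")
        assert table.loc[0, "informal_to_home_care_ratio"] == pytest.approx(3.0)
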