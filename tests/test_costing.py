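"""Unit-costing, micro-costing and perspective-separation checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ceatk import (
    CostSummary,
    MedicationRecord,
    TherapistCostParams,
    UnitCostTable,
    cost_group_session,
    cost_individual_session,
    cost_medications,
    cost_productivity,
    cost_services,
)
from ceatk.costing import cost_attendance_log

TABLE = UnitCostTable(costs={"gp_visit": 38.0, "inpatient_day": 400.0})
PARAMS = TherapistCostParams(hourly_employment_cost=25.0)


class TestServices:
    def test_empty_usage_is_free(self):
        assert cost_services({}, TABLE) == 0.0

    def test_arithmetic(self):
        assert cost_services({"gp_visit": 3, "inpatient_day": 2}, TABLE) == 914.0

    def test_blank_item_counts_as_zero_use(self):
        assert cost_services({"gp_visit": np.nan, "inpatient_day": 1}, TABLE) == 400.0

    def test_unpriced_codes_listed(self):
        with pytest.raises(KeyError, match="acupuncture.*reiki|reiki"):
            cost_services({"acupuncture": 1, "reiki": 2}, TABLE)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.integers(0, 20), b=st.integers(0, 20), k=st.floats(1, 5, allow_nan=False)
    )
    def test_linearity_in_counts(self, a, b, k):
        one = cost_services({"gp_visit": a, "inpatient_day": b}, TABLE)
        scaled = cost_services({"gp_visit": k * a, "inpatient_day": k * b}, TABLE)
        assert scaled == pytest.approx(k * one, rel=1e-12)


class TestTherapySessions:
    def test_individual_session_weighted_rate(self):
        assert cost_individual_session(PARAMS) == pytest.approx(47.75)

    def test_no_nondirect_weighting(self):
        p = TherapistCostParams(hourly_employment_cost=25.0, nondirect_ratio=0.0)
        assert cost_individual_session(p) == pytest.approx(25.0)

    def test_individual_session_linear_in_duration(self):
        p = TherapistCostParams(
            hourly_employment_cost=25.0, individual_session_minutes=30.0
        )
        assert cost_individual_session(p) == pytest.approx(23.875)

    def test_group_session_single_invitee(self):
        assert cost_group_session(1, PARAMS) == pytest.approx(119.375)

    def test_group_size_rule_selects_two_therapists(self):
        assert PARAMS.therapists_for(8) == 2
        assert PARAMS.therapists_for(3) == 1
        # 8 invitees: two therapists, conserved across invitees
        per = cost_group_session(8, PARAMS)
        assert per * 8 == pytest.approx(2 * 25.0 * 1.91 * 2.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cost_group_session(0, PARAMS)

    @settings(max_examples=100, deadline=None)
    @given(n=st.integers(1, 15), rate=st.floats(10, 90, allow_nan=False))
    def test_group_allocation_conserves_money_to_the_penny(self, n, rate):
        p = TherapistCostParams(hourly_employment_cost=rate)
        per = cost_group_session(n, p)
        total = p.therapists_for(n) * rate * 1.91 * 2.5
        assert per * n == pytest.approx(total, abs=0.005)


class TestMedications:
    def test_outside_window_is_free(self):
        rec = MedicationRecord("antidepressant", 0.10, start_day=400, finish_day=500)
        assert cost_medications([rec], window=(0, 365)) == 0.0

    def test_daily_cost_times_overlap(self):
        rec = MedicationRecord("antidepressant", 0.10, start_day=0, finish_day=30)
        assert cost_medications([rec], window=(0, 365)) == pytest.approx(3.0)

    def test_categories_add(self):
        recs = [
            MedicationRecord("antidepressant", 0.10, 0, 30),
            MedicationRecord("painkiller", 0.20, 10, 40),
        ]
        assert cost_medications(recs, (0, 365)) == pytest.approx(3.0 + 6.0)

    def test_reversed_dates_rejected(self):
        with pytest.raises(ValueError):
            MedicationRecord("antidepressant", 0.10, 30, 0)


class TestProductivity:
    def test_zero_hours(self):
        assert cost_productivity(0, 0, 13.5) == 0.0

    def test_human_capital_arithmetic(self):
        assert cost_productivity(40, 0, 13.5) == pytest.approx(540.0)

    def test_negative_hours_rejected(self):
        with pytest.raises(ValueError):
            cost_productivity(-1, 0, 13.5)


def test_nhs_pss_total_excludes_productivity():
    s = CostSummary(
        service_cost=100.0,
        intervention_cost=200.0,
        medication_cost=10.0,
        productivity_cost=5000.0,
    )
    assert s.total_nhs_pss == pytest.approx(310.0)


def _toy_attendance():
    # two participants in one group; pid 1 also has 2 individual attendances
    rows = []
    for pid, att in ((1, [1, 1]), (2, [0, 0])):
        for j, a in enumerate(att, start=1):
            rows.append((pid, "individual", j, np.nan, 1, a))
    for pid, invited, attended in ((1, [1, 1], [1, 0]), (2, [1, 0], [0, 0])):
        for j in (1, 2):
            rows.append((pid, "group", j, 0.0, invited[j - 1], attended[j - 1]))
    return pd.DataFrame(
        rows,
        columns=["pid", "session_type", "session_index", "group_id", "invited", "attended"],
    )


def test_attendance_log_costing_and_conservation():
    att = _toy_attendance()
    out = cost_attendance_log(att, PARAMS)
    per_ind = cost_individual_session(PARAMS)
    # session 1 has 2 invitees, session 2 has 1
    sess1 = PARAMS.therapists_for(2) * 25.0 * 1.91 * 2.5
    sess2 = PARAMS.therapists_for(1) * 25.0 * 1.91 * 2.5
    assert out.loc[1, "cost_intervention_individual"] == pytest.approx(2 * per_ind)
    assert out.loc[2, "cost_intervention_individual"] == 0.0
    assert out["cost_intervention_group"].sum() == pytest.approx(sess1 + sess2)
    assert out.loc[1, "group_sessions_attended"] == 1
    assert out.loc[2, "group_sessions_invited"] == 1


def test_zero_nondirect_ratio_strictly_lowers_intervention_cost():
    att = _toy_attendance()
    weighted = cost_attendance_log(att, PARAMS)
    unweighted = cost_attendance_log(
        att, TherapistCostParams(hourly_employment_cost=25.0, nondirect_ratio=0.0)
    )
    assert (unweighted["cost_intervention"] < weighted["cost_intervention"]).all()


def test_negative_unit_cost_rejected():
    with pytest.raises(ValueError):
        UnitCostTable(costs={"gp_visit": -1.0})
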