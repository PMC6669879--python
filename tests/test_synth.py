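"""Synthetic-trial generator: structure, determinism, injected truth."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ceatk import SimTruth, TrialDesign, apply_missingness, generate_trial
from ceatk.costing import DEFAULT_UNIT_COSTS
from ceatk.synth import _service_means, masked_columns, service_columns


def test_default_design_shape(default_trial):
    p = default_trial.participants
    assert len(p) == 250
    assert int(p["arm"].sum()) == 162
    assert {"eq5d_w0", "eq5d_w3", "hrsd_0", "gp_visit_i1"} <= set(p.columns)


def test_fixed_seed_reproduces_byte_identical_tables():
    a = generate_trial(TrialDesign(n_intervention=30, n_control=15, seed=4))
    b = generate_trial(TrialDesign(n_intervention=30, n_control=15, seed=4))
    assert a.participants.to_csv(index=False) == b.participants.to_csv(index=False)
    assert a.attendance.to_csv(index=False) == b.attendance.to_csv(index=False)
    c = generate_trial(TrialDesign(n_intervention=30, n_control=15, seed=5))
    assert a.participants.to_csv(index=False) != c.participants.to_csv(index=False)


def test_enlarging_one_arm_leaves_other_draws_untouched():
    small = generate_trial(TrialDesign(n_intervention=20, n_control=10, seed=9))
    large = generate_trial(TrialDesign(n_intervention=40, n_control=10, seed=9))
    cols = [c for c in small.participants.columns if c != "pid"]
    s_int = small.participants[small.participants.arm == 1][cols].reset_index(drop=True)
    l_int = large.participants[large.participants.arm == 1][cols].reset_index(drop=True)
    pd.testing.assert_frame_equal(s_int, l_int.iloc[: len(s_int)])
    s_ctl = small.participants[small.participants.arm == 0][cols].reset_index(drop=True)
    l_ctl = large.participants[large.participants.arm == 0][cols].reset_index(drop=True)
    pd.testing.assert_frame_equal(s_ctl, l_ctl)


def test_no_missingness_leaves_no_masked_blocks():
    t = generate_trial(
        TrialDesign(
            n_intervention=40,
            n_control=20,
            seed=3,
            true_effects=SimTruth(missing_fraction=0.0),
        )
    )
    cost_cols, outcome_cols = masked_columns(t.participants)
    svc = [c for c in cost_cols if not c.startswith("med_")]
    assert not t.participants[svc].isna().any().any()
    assert not t.participants[outcome_cols].isna().any().any()


def test_mcar_masked_fraction_matches_rate():
    t = generate_trial(
        TrialDesign(
            n_intervention=6500,
            n_control=3500,
            seed=2,
            true_effects=SimTruth(missing_mechanism="MCAR", missing_fraction=0.5),
        )
    )
    frac = t.participants["gp_visit_i1"].isna().mean()
    assert abs(frac - 0.5) < 0.02


class TestMarMissingness:
    def test_marginal_fraction_and_severity_dependence(self, big_trial):
        p = big_trial.participants
        miss = p["gp_visit_i1"].isna()
        assert abs(miss.mean() - 0.30) < 0.02
        # masked participants are sicker at baseline
        assert p.loc[miss, "hrsd_0"].mean() > p.loc[~miss, "hrsd_0"].mean()
        # logistic regression recovers a clearly nonzero slope
        X = sm.add_constant(p["sev_z"].to_numpy())
        fit = sm.Logit(miss.to_numpy().astype(float), X).fit(disp=0)
        assert fit.params[1] > 0
        assert fit.params[1] / fit.bse[1] > 5

    def test_mechanism_validation(self):
        with pytest.raises(ValueError, match="missing_mechanism"):
            SimTruth(missing_mechanism="MNAR")

    def test_zero_rate_is_identity(self, default_trial):
        full = default_trial.participants.dropna()
        out = apply_missingness(full, SimTruth(missing_fraction=0.0), seed=1)
        pd.testing.assert_frame_equal(out, full)


def test_generated_cost_moments_match_targets(big_trial):
    p = big_trial.participants
    truth = big_trial.design.true_effects
    ctrl_means, int_means = _service_means(truth)
    for arm, means in ((0, ctrl_means), (1, int_means)):
        sub = p[p.arm == arm]
        cost = np.zeros(len(sub))
        for code in means:
            cost += (
                sub[[f"{code}_i1", f"{code}_i2"]].to_numpy(dtype=float).sum(axis=1)
                * DEFAULT_UNIT_COSTS[code]
            )
        cost = cost[~np.isnan(cost)]
        target = sum(m * DEFAULT_UNIT_COSTS[c] for c, m in means.items())
        se = cost.std() / np.sqrt(len(cost))
        assert abs(cost.mean() - target) < 3 * se


def test_attendance_means_match_trial_report(big_trial):
    att = big_trial.attendance
    ind = att[att.session_type == "individual"].groupby("pid")["attended"].sum()
    grp = att[att.session_type == "group"].groupby("pid")
    assert ind.mean() == pytest.approx(22.8, abs=0.4)
    assert grp["attended"].sum().mean() == pytest.approx(19.3, abs=0.8)
    assert grp["invited"].sum().mean() == pytest.approx(24.4, abs=0.8)


def test_intervention_cost_calibration(big_trial):
    from ceatk.costing import cost_attendance_log

    out = cost_attendance_log(big_trial.attendance, big_trial.therapist_params)
    se = out["cost_intervention"].std() / np.sqrt(len(out))
    assert abs(out["cost_intervention"].mean() - 5000.0) < 3 * se


def test_normal_cost_family_emits_aggregate_costs():
    t = generate_trial(
        TrialDesign(
            n_intervention=400,
            n_control=200,
            seed=8,
            true_effects=SimTruth(missing_fraction=0.0, cost_family="normal"),
        )
    )
    p = t.participants
    assert "other_care_i1" in p.columns
    assert "gp_visit_i1" not in p.columns
    ctrl = p[p.arm == 0][["other_care_i1", "other_care_i2"]].sum(axis=1)
    se = ctrl.std() / np.sqrt(len(ctrl))
    assert abs(ctrl.mean() - 3300.0) < 3 * se


def test_design_validation_names_offending_field():
    with pytest.raises(ValueError, match="waves"):
        TrialDesign(waves=(0.0, 7.0, 12.0))
    with pytest.raises(ValueError, match="increasing"):
        TrialDesign(waves=(0.0, 12.0, 7.0, 18.0))
    with pytest.raises(ValueError, match="missing_fraction"):
        SimTruth(missing_fraction=1.2)
    with pytest.raises(ValueError, match="cost_dispersion"):
        SimTruth(cost_dispersion=0.0)
    with pytest.raises(ValueError, match="at least"):
        TrialDesign(n_intervention=2, n_control=1)


def test_service_columns_cover_all_intervals():
    cols = service_columns()
    assert "inpatient_day_i0" in cols and "talking_therapy_i3" in cols
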