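"""Adjusted differences, nested bootstrap, ICER, CEAC and quadrants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ceatk import (
    AdjustmentSpec,
    BootstrapCloud,
    adjusted_difference,
    bootstrap_cloud,
    ceac,
    icer,
    quadrant_shares,
)
from ceatk.cea import quadrant_label


def _frame(n=400, effect=0.0, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    arm = np.repeat([1, 0], [n * 2 // 3, n - n * 2 // 3])
    x = rng.normal(0, 1, n)
    y = effect * arm + 0.5 * x + rng.normal(0, sd, n)
    return pd.DataFrame({"arm": arm, "x": x, "y": y})


class TestAdjustedDifference:
    def test_null_case_within_noise(self):
        df = _frame(n=600, effect=0.0, seed=1)
        coef, fit = adjusted_difference(df, AdjustmentSpec("y", ()))
        assert abs(coef) < 3 * fit.bse[1]

    def test_recovers_injected_arm_effect(self):
        df = _frame(n=2000, effect=5000.0, seed=2, sd=3000.0)
        coef, fit = adjusted_difference(df, AdjustmentSpec("y", ("x",)))
        assert abs(coef - 5000.0) < 3 * fit.bse[1]

    def test_covariate_uncorrelated_with_arm_barely_moves_estimate(self):
        df = _frame(n=5000, effect=2.0, seed=3)
        unadj, _ = adjusted_difference(df, AdjustmentSpec("y", ()))
        adj, fit = adjusted_difference(df, AdjustmentSpec("y", ("x",)))
        assert abs(adj - unadj) < fit.bse[1]

    def test_constant_covariate_named_in_error(self):
        df = _frame(n=50)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            adjusted_difference(df, AdjustmentSpec("y", ("flat",)))

    def test_collinear_design_rejected(self):
        df = _frame(n=50)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="collinear"):
            adjusted_difference(df, AdjustmentSpec("y", ("x", "x2")))


class TestBootstrapCloud:
    def test_identity_resample_collapses_to_point_estimates(self):
        df = _frame(n=200, effect=3.0, seed=4)
        spec = AdjustmentSpec("y", ("x",))
        coef, _ = adjusted_difference(df, spec)
        cloud = bootstrap_cloud([df], spec, spec, B=1, seed=0, resample=False)
        assert len(cloud) == 1
        assert cloud.delta_cost[0] == pytest.approx(coef, rel=1e-9)
        assert cloud.delta_effect[0] == pytest.approx(coef, rel=1e-9)

    def test_cloud_size_is_m_times_b(self):
        df = _frame(n=120, seed=5)
        spec = AdjustmentSpec("y", ("x",))
        cloud = bootstrap_cloud([df, df.copy(), df.copy()], spec, spec, B=40, seed=1)
        assert len(cloud) == 120
        assert cloud.m == 3 and cloud.B_per_dataset == 40

    def test_deterministic_under_fixed_seed(self):
        df = _frame(n=150, seed=6)
        spec = AdjustmentSpec("y", ("x",))
        c1 = bootstrap_cloud([df], spec, spec, B=50, seed=9)
        c2 = bootstrap_cloud([df], spec, spec, B=50, seed=9)
        np.testing.assert_array_equal(c1.delta_cost, c2.delta_cost)
        c3 = bootstrap_cloud([df], spec, spec, B=50, seed=10)
        assert not np.array_equal(c1.delta_cost, c3.delta_cost)

    def test_percentile_ci_brackets_analytic_ols_ci(self):
        df = _frame(n=2000, effect=5000.0, seed=7, sd=3000.0)
        spec = AdjustmentSpec("y", ("x",))
        _, fit = adjusted_difference(df, spec)
        lo_a, hi_a = fit.conf_int()[1]
        cloud = bootstrap_cloud([df], spec, spec, B=2000, seed=3)
        lo_b, hi_b = np.percentile(cloud.delta_cost, [2.5, 97.5])
        width_a, width_b = hi_a - lo_a, hi_b - lo_b
        assert abs(width_b - width_a) / width_a < 0.10
        assert abs(lo_b - lo_a) < 0.1 * width_a
        assert abs(hi_b - hi_a) < 0.1 * width_a


class TestIcer:
    def test_cost_per_qaly_anchor(self):
        assert icer(7048.0, 0.032) == pytest.approx(220250.0, abs=1e-6)

    def test_cost_per_symptom_point(self):
        assert icer(7048.0, 1.0) == 7048.0

    def test_zero_effect_undefined(self):
        with pytest.raises(ValueError):
            icer(100.0, 0.0)

    def test_dominance_labels(self):
        assert "dominant" in quadrant_label(-10.0, 0.5)
        assert "dominated" in quadrant_label(10.0, -0.5)
        assert "north-east" in quadrant_label(10.0, 0.5)
        assert quadrant_label(10.0, 0.0) == "undefined"

    @settings(max_examples=100, deadline=None)
    @given(
        dc=st.floats(-1e5, 1e5, allow_nan=False),
        de=st.floats(-10, 10, allow_nan=False).filter(lambda v: abs(v) > 1e-6),
    )
    def test_identity(self, dc, de):
        assert icer(dc, de) * de == pytest.approx(dc, rel=1e-9, abs=1e-9)


def _cloud(dc, de):
    dc = np.asarray(dc, dtype=float)
    return BootstrapCloud(dc, np.asarray(de, dtype=float), B_per_dataset=len(dc), m=1)


class TestCeacAndQuadrants:
    def test_degenerate_cloud_at_trial_estimate_fails_nice_threshold(self):
        cloud = _cloud([7048.0] * 100, [0.032] * 100)
        assert ceac(cloud, [30_000.0])[30_000.0] == 0.0

    def test_lambda_zero_equals_probability_of_saving_money(self):
        rng = np.random.default_rng(0)
        cloud = _cloud(rng.normal(100, 500, 4000), rng.normal(0, 1, 4000))
        assert ceac(cloud, [0.0])[0.0] == float(np.mean(cloud.delta_cost < 0))

    def test_large_lambda_tends_to_probability_of_any_gain(self):
        rng = np.random.default_rng(1)
        cloud = _cloud(rng.normal(100, 500, 4000), rng.normal(0.05, 1, 4000))
        assert ceac(cloud, [1e12])[1e12] == float(np.mean(cloud.delta_effect > 0))

    def test_probabilities_bounded(self):
        rng = np.random.default_rng(2)
        cloud = _cloud(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        curve = ceac(cloud, np.arange(0, 50_001, 500))
        assert all(0.0 <= v <= 1.0 for v in curve.values())

    def test_empty_lambda_grid_rejected(self):
        cloud = _cloud([1.0], [1.0])
        with pytest.raises(ValueError):
            ceac(cloud, [])

    def test_all_costlier_replicates_fill_upper_half_plane(self):
        rng = np.random.default_rng(3)
        cloud = _cloud(np.abs(rng.normal(5, 1, 1000)) + 0.1, rng.normal(0, 1, 1000))
        shares = quadrant_shares(cloud)
        assert shares["NE"] + shares["NW"] == pytest.approx(1.0)

    def test_symmetric_cloud_splits_evenly(self):
        rng = np.random.default_rng(4)
        cloud = _cloud(rng.normal(0, 1, 40_000), rng.normal(0, 1, 40_000))
        shares = quadrant_shares(cloud)
        for v in shares.values():
            assert v == pytest.approx(0.25, abs=0.01)

    def test_single_replicate_in_north_east(self):
        shares = quadrant_shares(_cloud([10.0], [0.5]))
        assert shares == {"NE": 1.0, "NW": 0.0, "SE": 0.0, "SW": 0.0}

    def test_shares_always_sum_to_one_with_ties(self):
        cloud = _cloud([0.0, 1.0, -1.0, 0.0], [0.0, 0.5, 0.0, -0.5])
        assert sum(quadrant_shares(cloud).values()) == pytest.approx(1.0)


def test_cloud_validates_size_and_finiteness():
    with pytest.raises(ValueError):
        BootstrapCloud(np.array([1.0]), np.array([1.0, 2.0]), 1, 1)
    with pytest.raises(ValueError):
        BootstrapCloud(np.array([np.inf]), np.array([1.0]), 1, 1)
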