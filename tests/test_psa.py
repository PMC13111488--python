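import numpy as np
import pandas as pd
import pytest

from orthocea import (
    CalibrationError,
    OutcomeProbabilities,
    ValidationError,
    calibrate_dirichlet,
    ce_scatter,
    cost_draw_frame,
    evaluate_arm,
    run_psa,
    sample_outcome_matrix,
    sample_outcomes,
)

QH_CENTER = OutcomeProbabilities(0.821, 0.087, 0.092)


class TestCalibration:
    def test_quad_helix_concentration_closed_form(self):
        spec = calibrate_dirichlet(QH_CENTER, target_sd=0.05)
        assert spec.concentration == pytest.approx(0.821 * 0.179 / 0.0025 - 1)
        assert spec.concentration == pytest.approx(57.7836, abs=1e-4)
        assert sum(spec.alpha) == pytest.approx(spec.concentration)

    def test_symmetric_center_concentration(self):
        spec = calibrate_dirichlet(
            OutcomeProbabilities(1 / 3, 1 / 3, 1 / 3), target_sd=0.05
        )
        assert spec.concentration == pytest.approx((2 / 9) / 0.0025 - 1)
        assert spec.concentration == pytest.approx(87.8889, abs=1e-3)

    def test_marginal_sd_closed_form_is_exact(self):
        """Under Dirichlet(a0 * center) the success marginal is Beta with
        variance p(1-p)/(a0+1); calibration must invert this exactly."""
        spec = calibrate_dirichlet(QH_CENTER, target_sd=0.05)
        p = QH_CENTER.p_success
        implied_sd = np.sqrt(p * (1 - p) / (spec.concentration + 1))
        assert implied_sd == pytest.approx(0.05, abs=1e-12)

    def test_infeasible_dispersion_rejected(self):
        limit = np.sqrt(0.821 * 0.179)
        with pytest.raises(CalibrationError):
            calibrate_dirichlet(QH_CENTER, target_sd=limit)
        with pytest.raises(CalibrationError):
            calibrate_dirichlet(QH_CENTER, target_sd=0.0)

    def test_degenerate_center_instructs_exclusion(self):
        with pytest.raises(CalibrationError):
            calibrate_dirichlet(OutcomeProbabilities(1.0, 0.0, 0.0))


class TestSampling:
    def test_draws_lie_on_simplex(self):
        spec = calibrate_dirichlet(QH_CENTER)
        draws = sample_outcome_matrix(spec, 2000, np.random.default_rng(0))
        assert np.all(draws >= 0)
        assert np.allclose(draws.sum(axis=1), 1.0, atol=1e-9)
        single = sample_outcomes(spec, np.random.default_rng(0))
        single.validate()

    def test_success_marginal_sd_near_target(self):
        spec = calibrate_dirichlet(QH_CENTER, target_sd=0.05)
        draws = sample_outcome_matrix(spec, 10_000, np.random.default_rng(11))
        assert draws[:, 0].std(ddof=1) == pytest.approx(0.05, abs=0.005)

    def test_about_95_percent_within_ten_points(self):
        spec = calibrate_dirichlet(QH_CENTER, target_sd=0.05)
        draws = sample_outcome_matrix(spec, 10_000, np.random.default_rng(11))
        coverage = np.mean(np.abs(draws[:, 0] - 0.821) <= 0.10)
        assert coverage == pytest.approx(0.95, abs=0.02)


class TestRunPsa:
    def test_single_iteration_inside_pathway_hull(self, arms, timing, baseline):
        result = run_psa(arms, timing, n_iterations=1, seed=5)
        for name, frame in result.draws.items():
            assert len(frame) == 1
            arm = next(a for a in arms if a.name == name)
            low = arm.initial_cost
            high = arm.initial_cost + baseline.initial_cost
            assert low <= frame["cost"].iloc[0] <= high
            assert 0 <= frame["effect"].iloc[0] <= 1

    def test_baseline_required_and_not_varied(self, arms, timing):
        interceptive_only = [a for a in arms if not a.is_baseline]
        with pytest.raises(ValidationError):
            run_psa(interceptive_only, timing, n_iterations=10)
        result = run_psa(arms, timing, n_iterations=10, seed=1)
        assert "fixed_appliance" not in result.draws
        assert result.baseline.expected_cost == 2501

    def test_identical_seed_bitwise_identical(self, arms, timing):
        first = run_psa(arms, timing, n_iterations=500, seed=99)
        second = run_psa(arms, timing, n_iterations=500, seed=99)
        pd.testing.assert_frame_equal(first.summary(), second.summary())
        for name in first.draws:
            pd.testing.assert_frame_equal(first.draws[name], second.draws[name])

    def test_appending_an_arm_preserves_substreams(self, arms, timing):
        import dataclasses

        clone = dataclasses.replace(arms[1], name="clone")
        result_small = run_psa(arms, timing, n_iterations=200, seed=7)
        result_large = run_psa(arms + [clone], timing, n_iterations=200, seed=7)
        for name in result_small.draws:
            pd.testing.assert_frame_equal(result_small.draws[name], result_large.draws[name])

    def test_mean_within_monte_carlo_error_of_base_case(self, arms, timing):
        """The tree is linear in the outcome probabilities and the Dirichlet
        mean is the centre, so PSA means estimate the base case."""
        result = run_psa(arms, timing, n_iterations=10_000, seed=3)
        summary = result.summary().set_index("arm")
        for name in result.draws:
            base = result.base_case[name]
            row = summary.loc[name]
            assert abs(row["mean_cost"] - base.expected_cost) <= 3 * row["se_cost"]
            assert abs(row["mean_effect"] - base.expected_effect) <= 3 * row["se_effect"]


class TestScatter:
    def test_draws_overwhelmingly_southwest(self, arms, timing):
        result = run_psa(arms, timing, n_iterations=5000, seed=17)
        scatter = ce_scatter(result)
        points = scatter[~scatter["is_mean"]]
        southwest = (points["quadrant"] == "southwest").mean()
        assert southwest >= 0.99

    def test_baseline_absent_and_counts_match(self, arms, timing):
        result = run_psa(arms, timing, n_iterations=50, seed=2)
        scatter = ce_scatter(result)
        assert "fixed_appliance" not in set(scatter["arm"])
        points = scatter[~scatter["is_mean"]]
        assert points.groupby("arm").size().eq(50).all()
        means = scatter[scatter["is_mean"]]
        assert len(means) == len(result.draws)

    def test_single_draw_scatter(self, arms, timing):
        result = run_psa(arms, timing, n_iterations=1, seed=2)
        scatter = ce_scatter(result)
        points = scatter[~scatter["is_mean"]]
        assert points.groupby("arm").size().eq(1).all()

    def test_cost_draw_frame_long_format(self, arms, timing):
        result = run_psa(arms, timing, n_iterations=20, seed=2)
        frame = cost_draw_frame(result)
        assert set(frame.columns) == {"arm", "draw", "cost"}
        assert len(frame) == 20 * len(result.draws)
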