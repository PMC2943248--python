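"""Scoring-model simulation: calibration, closed forms, and Monte Carlo."""

import math

import numpy as np
import pytest

from panelcalc import (
    MeanDrawSpec,
    SimConfig,
    broad_model,
    calibrate_separation,
    conditional_error_probability,
    conditional_sum_rule_curve,
    grant_accuracy_curve,
    grant_model,
    judge_accuracy_from_separation,
    majority_accuracy,
    simulate_accuracy_curve,
    tight_model,
)


class TestJudgeAccuracy:
    def test_published_calibration(self):
        """c = 1.16 at cv 0.2 puts a judge near 70%."""
        assert judge_accuracy_from_separation(1.16, 0.2) == pytest.approx(0.699, abs=0.001)

    def test_no_separation_means_chance(self):
        for cv in (0.1, 0.2, 1.0):
            assert judge_accuracy_from_separation(1.0, cv) == pytest.approx(0.5)

    def test_derived_value_against_numerical_integration(self):
        """Frozen from numerically integrating P(S_A > S_B) over the score
        densities at judge means 1, 7 and 700 — identical for all three,
        confirming mean-independence."""
        assert judge_accuracy_from_separation(1.385, 0.2) == pytest.approx(0.8701, abs=1e-4)

    def test_mean_independence_by_direct_simulation(self):
        rng = np.random.default_rng(7)
        c, cv = 1.3, 0.2
        expected = judge_accuracy_from_separation(c, cv)
        for mean in (0.5, 7.0, 700.0):
            b = rng.normal(mean, cv * mean, 200_000)
            a = rng.normal(c * mean, cv * c * mean, 200_000)
            assert (a > b).mean() == pytest.approx(expected, abs=0.004)


class TestCalibrateSeparation:
    def test_seventy_percent_gives_printed_constant(self):
        assert calibrate_separation(0.70, 0.2) == pytest.approx(1.1607, abs=5e-4)

    def test_sixty_five_percent(self):
        assert calibrate_separation(0.65, 0.2) == pytest.approx(1.1155, abs=5e-4)

    @pytest.mark.parametrize("target", [0.55, 0.65, 0.75, 0.85, 0.95])
    def test_round_trip(self, target):
        c = calibrate_separation(target, 0.2)
        assert judge_accuracy_from_separation(c, 0.2) == pytest.approx(target, abs=1e-10)

    def test_limit_toward_chance(self):
        assert calibrate_separation(0.5001, 0.2) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("bad", [0.5, 0.49, 1.0, 1.1])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            calibrate_separation(bad, 0.2)


class TestMeanDraw:
    def test_lognormal_moment_conversion(self):
        """Requested (mean, sd) are moments of the lognormal itself."""
        spec = MeanDrawSpec("lognormal", 700.0, 1400.0)
        rng = np.random.default_rng(0)
        draws = spec.sample(rng, 1_000_000)
        assert draws.mean() == pytest.approx(700.0, rel=0.05)
        assert draws.std() == pytest.approx(1400.0, rel=0.05)

    def test_normal_draws_are_positive(self):
        spec = MeanDrawSpec("normal", 2.0, 0.5)
        draws = spec.sample(np.random.default_rng(1), 500_000)
        assert (draws > 0).all()

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            MeanDrawSpec("uniform", 1.0, 1.0)


class TestSimulateAccuracyCurve:
    def test_rules_coincide_for_single_judge(self):
        config = SimConfig(n_values=(1,), seed=11, n_panels=40_000)
        model = tight_model(calibrate_separation(0.70, 0.2))
        expected = model.judge_accuracy
        for rule in ("sum", "majority"):
            est, se = simulate_accuracy_curve(model, rule, config).points[1]
            assert abs(est - expected) < 3 * se

    def test_majority_simulation_matches_analytic_curve(self):
        """Cross-module oracle: each judge's correctness is Bernoulli with
        the closed-form accuracy, so the simulated majority curve must agree
        with the binomial formula."""
        c = calibrate_separation(0.70, 0.2)
        p = judge_accuracy_from_separation(c, 0.2)
        config = SimConfig(n_values=(1, 3, 5, 9), seed=5, n_panels=50_000)
        for model in (tight_model(c), broad_model(c)):
            est = simulate_accuracy_curve(model, "majority", config)
            for n, (val, se) in est.points.items():
                assert abs(val - majority_accuracy(p, n)) < 3 * se

    def test_sum_beats_majority_under_tight_model(self):
        c = calibrate_separation(0.70, 0.2)
        config = SimConfig(n_values=(9,), seed=3, n_panels=50_000)
        s = simulate_accuracy_curve(tight_model(c), "sum", config).points[9][0]
        m = simulate_accuracy_curve(tight_model(c), "majority", config).points[9][0]
        assert s > m

    def test_majority_beats_sum_under_broad_model(self):
        c = calibrate_separation(0.70, 0.2)
        config = SimConfig(n_values=(9,), seed=3, n_panels=50_000)
        s = simulate_accuracy_curve(broad_model(c), "sum", config).points[9][0]
        m = simulate_accuracy_curve(broad_model(c), "majority", config).points[9][0]
        assert m > s

    def test_reproducible_for_fixed_seed(self):
        config = SimConfig(n_values=(3, 5), seed=42, n_panels=10_000)
        a = simulate_accuracy_curve(tight_model(1.2), "sum", config)
        b = simulate_accuracy_curve(tight_model(1.2), "sum", config)
        assert a.points == b.points

    def test_majority_rejects_even_panels(self):
        with pytest.raises(ValueError):
            simulate_accuracy_curve(
                tight_model(1.2), "majority", SimConfig(n_values=(4,), seed=0, n_panels=10)
            )


class TestConditionalErrorProbability:
    def test_single_judge_consistency(self):
        """For one judge the conditional error equals 1 - closed-form
        accuracy, whatever the judge's mean."""
        for m in (0.5, 2.0, 700.0):
            assert conditional_error_probability([m], 1.16, 0.2) == pytest.approx(
                1.0 - judge_accuracy_from_separation(1.16, 0.2), abs=1e-12
            )

    def test_vanishes_for_large_equal_panels(self):
        assert conditional_error_probability([2.0] * 400, 1.2, 0.2) < 1e-8

    def test_agrees_with_raw_monte_carlo(self):
        """Rao-Blackwellized estimate vs raw panel simulation (paired seeds)."""
        c = calibrate_separation(0.70, 0.2)
        config = SimConfig(n_values=(9,), seed=17, n_panels=60_000)
        raw_est, raw_se = simulate_accuracy_curve(tight_model(c), "sum", config).points[9]
        cond_est, cond_se = conditional_sum_rule_curve(tight_model(c), config).points[9]
        assert abs(raw_est - cond_est) < 3 * math.hypot(raw_se, cond_se)

    def test_variance_reduction(self):
        c = calibrate_separation(0.70, 0.2)
        config = SimConfig(n_values=(9,), seed=17, n_panels=60_000)
        raw_se = simulate_accuracy_curve(tight_model(c), "sum", config).points[9][1]
        cond_se = conditional_sum_rule_curve(tight_model(c), config).points[9][1]
        assert cond_se < raw_se

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            conditional_error_probability([], 1.2, 0.2)
        with pytest.raises(ValueError):
            conditional_error_probability([1.0, -1.0], 1.2, 0.2)


class TestGrantCurve:
    def test_single_reviewer_matches_closed_form(self):
        config = SimConfig(n_values=(1,), seed=2, n_panels=20_000)
        est, se = grant_accuracy_curve(1.3, config).points[1]
        assert abs(est - judge_accuracy_from_separation(1.3, 0.2)) < max(3 * se, 1e-9)

    def test_accuracy_increases_with_separation(self):
        config = SimConfig(n_values=(10,), seed=4, n_panels=20_000)
        vals = [grant_accuracy_curve(c, config).points[10][0] for c in (1.1, 1.2, 1.3, 1.4)]
        assert vals == sorted(vals)

    def test_curve_increases_with_panel_size(self):
        c = calibrate_separation(0.70, 0.2)
        config = SimConfig(n_values=(1, 3, 5, 11), seed=4, n_panels=20_000)
        curve = grant_accuracy_curve(c, config)
        vals = [curve.points[n][0] for n in (1, 3, 5, 11)]
        assert vals == sorted(vals)

    def test_even_panels_allowed(self):
        config = SimConfig(n_values=(10,), seed=0, n_panels=1_000)
        assert 0.5 < grant_accuracy_curve(1.2, config).points[10][0] < 1.0
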