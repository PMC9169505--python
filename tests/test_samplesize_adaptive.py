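import math

import numpy as np
import pytest

from asbtrial.samplesize_adaptive import (AdaptiveState, DeltaStatus, Stage,
                                          adaptive_decision, icc,
                                          n_cv_difference, n_dose_contrast,
                                          n_repeated_measures,
                                          posterior_sample_size,
                                          processed_delta_update,
                                          samplesize_grid,
                                          uncertainty_reduction)

ONLINE_MEANS = [5, 4.83, 5, 5.17, 5.17, 5.5, 5.67, 5.67, 5.67, 5.67, 5.83]
CONTRASTS = [-4, -4, 0.5, 0.5, 1, 1, 1, 1, 1, 1, 1]


class TestCalculators:
    def test_cv_difference_pilot_inputs(self):
        res = n_cv_difference(0.0598, 0.367, alpha=0.05, power=0.80)
        assert res.n == 12
        assert res.n_raw == pytest.approx(
            2.801585 ** 2 * (0.0598 ** 2 + 0.367 ** 2) / (0.367 - 0.0598) ** 2,
            rel=1e-5)

    def test_cv_gap_scaling(self):
        # doubling the CV gap at fixed cv-square sum quarters n:
        # (0.3, 0.5) and (0.1606..., 0.5606...) share cv1^2+cv2^2 = 0.34
        # while the second pair has twice the gap
        base = n_cv_difference(0.3, 0.5, power=0.80)
        cv1 = (-0.8 + math.sqrt(0.64 + 1.44)) / 4
        wide = n_cv_difference(cv1, cv1 + 0.4, power=0.80)
        assert wide.n_raw == pytest.approx(base.n_raw / 4, rel=1e-6)

    def test_repeated_measures_pilot_inputs(self):
        res = n_repeated_measures(1.18014, 0.07398, 11, 0.4,
                                  alpha=0.05, power=0.80, groups=2)
        assert res.n == 19

    def test_icc_zero_reduces_to_two_mean_formula(self):
        res0 = n_repeated_measures(1.0, 0.0, 10, 0.5, groups=2)
        classic = 2 * (1.959964 + 0.841621) ** 2 * 1.0 / 0.5 ** 2
        assert res0.n_raw == pytest.approx(classic / 10, rel=1e-5)

    def test_n_nondecreasing_in_icc(self):
        ns = [n_repeated_measures(1.0, r, 10, 0.5).n_raw
              for r in (0, 0.2, 0.5, 0.9)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_dose_contrast_pilot_inputs(self):
        res = n_dose_contrast(ONLINE_MEANS, CONTRASTS, 0.547,
                              alpha=0.05, power=0.90)
        assert res.n == 10

    def test_contrast_scale_invariance(self):
        a = n_dose_contrast(ONLINE_MEANS, CONTRASTS, 0.547, power=0.9)
        scaled = [3 * c for c in CONTRASTS]
        b = n_dose_contrast(ONLINE_MEANS, scaled, 0.547, power=0.9)
        assert a.n_raw == pytest.approx(b.n_raw)

    def test_orthogonal_contrast_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            n_dose_contrast([1, 1, 1], [1, -2, 1], 0.5)

    def test_contrasts_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to 0"):
            n_dose_contrast([1, 2, 3], [1, 1, 1], 0.5)

    def test_equal_cvs_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            n_cv_difference(0.3, 0.3)

    @pytest.mark.parametrize("fn,kw", [
        (n_cv_difference, dict(cv1=0.06, cv2=0.37)),
        (n_repeated_measures, dict(sigma2_total=1.2, icc=0.07, m=11, delta=0.4)),
        (n_dose_contrast, dict(means=ONLINE_MEANS, contrasts=CONTRASTS,
                               sigma2=0.547)),
    ])
    def test_monotone_in_power_and_alpha(self, fn, kw):
        assert fn(power=0.90, **kw).n >= fn(power=0.80, **kw).n
        assert fn(alpha=0.01, **kw).n >= fn(alpha=0.10, **kw).n

    def test_effect_monotonicity(self):
        small = n_repeated_measures(1.0, 0.1, 11, 0.2)
        large = n_repeated_measures(1.0, 0.1, 11, 0.8)
        assert small.n >= large.n

    def test_grid_shape(self):
        grid = samplesize_grid("cv_difference", cv1=0.0598, cv2=0.367)
        assert grid.shape == (4, 3)
        assert grid.loc["80%", "5%"] == 12

    def test_icc_pilot_components(self):
        assert icc(0.08731, 1.09283) == pytest.approx(0.07398, abs=5e-6)


class TestPosteriorSampleSize:
    def test_point_mass_matches_conventional(self):
        res = posterior_sample_size(
            {"sigma2_total": np.full(300, 1.18014)}, "repeated_measures",
            icc=0.07398, m=11, delta=0.4)
        assert res.n == 19
        assert res.sequential_plan == [19, 19, 19, 19]
        assert res.excluded_fraction == 0

    def test_stochastically_larger_delta_shrinks_n(self):
        rng = np.random.default_rng(0)
        small = rng.uniform(0.3, 0.4, 400)
        large = small + 0.2
        n_small = posterior_sample_size({"delta": small}, "repeated_measures",
                                        sigma2_total=1.2, icc=0.07, m=11)
        n_large = posterior_sample_size({"delta": large}, "repeated_measures",
                                        sigma2_total=1.2, icc=0.07, m=11)
        assert np.median(n_large.distribution) < np.median(n_small.distribution)

    def test_gamma_sigma2_median_consistency(self):
        rng = np.random.default_rng(1)
        shape = 8.0
        draws = rng.gamma(shape, 1.18014 / shape, 2000)
        res = posterior_sample_size({"sigma2_total": draws},
                                    "repeated_measures",
                                    icc=0.07398, m=11, delta=0.4)
        at_median = n_repeated_measures(float(np.median(draws)), 0.07398,
                                        11, 0.4).n
        assert abs(np.median(res.distribution) - at_median) <= 2

    def test_precondition_violations_counted(self):
        deltas = np.array([0.4, -0.1, 0.5, 0.0])
        res = posterior_sample_size({"delta": deltas}, "repeated_measures",
                                    sigma2_total=1.0, icc=0.1, m=11)
        assert res.excluded_fraction == 0.5

    def test_plan_nondecreasing(self):
        rng = np.random.default_rng(2)
        res = posterior_sample_size(
            {"sigma2_total": rng.gamma(4, 0.3, 500)}, "repeated_measures",
            icc=0.07, m=11, delta=0.4)
        plan = res.sequential_plan
        assert plan == sorted(plan)


class TestUncertaintyReduction:
    def test_halved_sd_gives_50(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200000)
        b = rng.normal(0, 0.5, 200000)
        res = uncertainty_reduction(a, b)
        assert res["UR"] == pytest.approx(50, abs=1.5)
        assert res["equivalent"]

    def test_identical_posteriors(self):
        rng = np.random.default_rng(4)
        a = rng.normal(2, 1, 50000)
        res = uncertainty_reduction(a, a)
        assert res["R"] == 1.0
        assert res["UR"] == 0.0
        assert res["equivalent"]

    def test_root_n_scaling_five_vs_twenty(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal(20)
        post5 = data[:5].mean() + rng.standard_normal(200000) / np.sqrt(5)
        post20 = data.mean() + rng.standard_normal(200000) / np.sqrt(20)
        res = uncertainty_reduction(post5, post20)
        assert res["UR"] == pytest.approx(50, abs=3)

    def test_cv_mode(self):
        rng = np.random.default_rng(6)
        a = rng.normal(10, 2, 100000)
        b = rng.normal(10, 1, 100000)
        res = uncertainty_reduction(a, b, mode="cv")
        assert res["UR"] == pytest.approx(50, abs=2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            uncertainty_reduction(np.full(10, 1.0), np.full(10, 2.0))


class TestDeltaStateMachine:
    def wide(self, rng):
        return rng.normal(0.4, 1.0, 4000)

    def narrow(self, rng, mean=0.4):
        return rng.normal(mean, 0.02, 4000)

    def test_wide_posterior_retains_anterior(self):
        rng = np.random.default_rng(7)
        state = processed_delta_update(AdaptiveState(), self.narrow(rng),
                                       self.wide(rng))
        assert state.delta_status is DeltaStatus.PROCESSED_UNCERTAIN
        assert state.interim == "N3"

    def test_shifted_narrow_posterior_replaces_delta(self):
        rng = np.random.default_rng(8)
        state = processed_delta_update(AdaptiveState(), self.narrow(rng, 0.4),
                                       self.narrow(rng, 0.6))
        assert state.delta_status is DeltaStatus.PROCESSED_CREDIBLE
        assert state.delta == pytest.approx(0.6, abs=0.01)

    def test_stable_narrow_posterior_validates(self):
        rng = np.random.default_rng(9)
        state = processed_delta_update(AdaptiveState(), self.narrow(rng, 0.4),
                                       self.narrow(rng, 0.4))
        assert state.delta_status is DeltaStatus.VALID
        assert state.stage is Stage.CONFIRMATORY

    def test_log_append_only(self):
        rng = np.random.default_rng(10)
        state = AdaptiveState()
        processed_delta_update(state, self.narrow(rng), self.wide(rng))
        processed_delta_update(state, self.narrow(rng), self.narrow(rng))
        assert len(state.log) == 2


class TestDecisionEngine:
    def valid_state(self):
        return AdaptiveState(delta_status=DeltaStatus.VALID, delta=0.4)

    def test_processed_delta_gates_everything(self):
        res = adaptive_decision(AdaptiveState(), 0.99, 0.99, 0.99)
        assert res["next_interim"] == "N3"
        assert "certainty ratio" in res["action"]

    def test_futility_stop(self):
        res = adaptive_decision(self.valid_state(), 0.5, 0.01)
        assert res["action"].startswith("stop")
        assert res["next_interim"] is None

    def test_h1_eliminates_pei_session(self):
        res = adaptive_decision(self.valid_state(), 0.97, 0.5)
        assert "eliminate PEI" in res["action"]
        assert res["next_interim"] == "N4"

    def test_credible_h2_and_dose_defines_doses(self):
        res = adaptive_decision(self.valid_state(), 0.5, 0.99, dose_prob=0.99)
        assert "min/max" in res["action"]

    def test_credible_h2_partial_dose_uses_n6(self):
        res = adaptive_decision(self.valid_state(), 0.5, 0.99, dose_prob=0.5)
        assert res["next_interim"] == "N6"

    def test_partial_dose_without_h2_uses_n5(self):
        res = adaptive_decision(self.valid_state(), 0.5, 0.5, dose_prob=0.5)
        assert res["next_interim"] == "N5"

    def test_dose_decision_requires_probability(self):
        with pytest.raises(ValueError, match="dose"):
            adaptive_decision(self.valid_state(), 0.5, 0.99, dose_prob=None)

    def test_pure_function(self):
        a = adaptive_decision(self.valid_state(), 0.6, 0.7, 0.5)
        b = adaptive_decision(self.valid_state(), 0.6, 0.7, 0.5)
        assert a == b

    def test_probability_bounds_checked(self):
        with pytest.raises(ValueError):
            adaptive_decision(self.valid_state(), 1.2, 0.5)
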