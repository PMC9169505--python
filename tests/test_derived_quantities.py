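import math

import numpy as np
import pytest
from scipy import optimize, stats

from asbtrial import simulate
from asbtrial.data_model import PosteriorDraws, RawTLQSeries, Treatment, Dataset
from asbtrial.derived_quantities import (StimulationTimeline,
                                         UndefinedDoseError, control_chart,
                                         dmin_dmax, dose_at, effective_doses,
                                         gain_and_carryover,
                                         minimum_clinical_efficacy_descriptive,
                                         minimum_clinical_efficacy_posterior,
                                         treatment_contrast)
from asbtrial.model_core import CurveParams


def logistic(j, c, f, d, e):
    return f + (c - f) / (1 + math.exp(-d * (j - e)))


class TestDminDmax:
    def test_example_against_root_finding(self):
        c, f, d, e, delta = 4, 2, 1, 11, 0.4
        dmin, dmax = dmin_dmax(c, f, d, e, delta)
        # independent oracle: solve G_O(j) = f + delta numerically
        root_min = optimize.brentq(lambda j: logistic(j, c, f, d, e) - (f + delta),
                                   -50, e)
        root_max = optimize.brentq(lambda j: logistic(j, c, f, d, e) - (c - delta),
                                   e, 80)
        assert dmin == pytest.approx(root_min, abs=1e-9)
        assert dmax == pytest.approx(root_max, abs=1e-9)
        assert dmin == pytest.approx(11 - math.log(4), abs=1e-12)

    def test_symmetry_about_inflection(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            delta = rng.uniform(0.05, 0.3)
            f = rng.uniform(2, 5)
            c = f + 2 * delta + rng.uniform(0.1, 3)
            d = rng.choice([-1, 1]) * rng.uniform(0.2, 3)
            e = rng.uniform(8, 14)
            dmin, dmax = dmin_dmax(c, f, d, e, delta)
            assert dmin + dmax == pytest.approx(2 * e, abs=1e-9)

    def test_delta_at_half_gain_collapses_to_inflection(self):
        c, f, d, e = 4, 2, 1, 11
        delta = (c - f) / 2 - 1e-9
        dmin, dmax = dmin_dmax(c, f, d, e, delta)
        assert dmin == pytest.approx(e, abs=1e-6)
        assert dmax == pytest.approx(e, abs=1e-6)

    def test_undefined_cases_named(self):
        with pytest.raises(UndefinedDoseError, match="nonzero"):
            dmin_dmax(4, 2, 0, 11, 0.4)
        with pytest.raises(UndefinedDoseError, match="2\\*delta"):
            dmin_dmax(4, 3.5, 1, 11, 0.4)


class TestGainCarryover:
    def test_values(self):
        p = CurveParams(a=5, b=0, c=4, d=1, e=11, f=2, g=5, h=1)
        gain, co = gain_and_carryover(p)
        assert gain == 2
        assert co == 0

    def test_posterior_linearity(self):
        rng = np.random.default_rng(1)
        cs, fs = rng.normal(4, 0.3, 500), rng.normal(2, 0.3, 500)
        gains = cs - fs
        assert gains.mean() == pytest.approx(cs.mean() - fs.mean())


class TestDelta:
    def make_pei_dataset(self, online_rise):
        """PEI series whose transformed online response exceeds PRE by
        ``online_rise`` exactly (raw drops by that amount at T6+)."""
        raw = [6] * 5 + [6 - online_rise] * 11 + [6 - online_rise] * 5
        s = RawTLQSeries("s1", 1, Treatment.PEI, raw)
        return Dataset([s])

    def test_displacement_halved(self):
        ds = self.make_pei_dataset(1)
        # transformed online sits 1 above PRE -> delta 0.5
        assert minimum_clinical_efficacy_descriptive(ds).delta == pytest.approx(0.5)

    def test_zero_effect_flagged(self):
        ds = self.make_pei_dataset(0)
        with pytest.raises(ValueError, match="not positive"):
            minimum_clinical_efficacy_descriptive(ds)

    def test_posterior_point_mass(self):
        draws = {f"beta_{p}_{c}": np.zeros((1, 50))
                 for p in "abcdefgh" for c in ("Intercept", "SP", "tP", "Start")}
        draws["beta_c_Intercept"] += 4.0
        draws["beta_f_Intercept"] += 3.0
        mce, delta_draws = minimum_clinical_efficacy_posterior(
            PosteriorDraws(draws))
        assert mce.delta == pytest.approx(0.5)
        assert np.all(delta_draws == 0.5)


class TestControlChart:
    def test_constant_series_collapses(self):
        res = control_chart([4, 4, 4, 4])
        assert res["lower"] == res["upper"] == res["center"] == 4
        assert res["out_of_limits"] == []

    def test_alternating_example(self):
        res = control_chart([4, 5, 4, 5, 4])
        assert res["center"] == pytest.approx(4.4)
        assert res["lower"] == pytest.approx(4.4 - 2.66)
        assert res["upper"] == pytest.approx(4.4 + 2.66)
        assert res["out_of_limits"] == []

    def test_gross_outlier_flagged(self):
        res = control_chart([5, 5.1, 4.9, 5, 5.05, 20])
        assert 5 in res["out_of_limits"]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            control_chart([1.0])


class TestContrast:
    def constant_diff_draws(self, diff):
        rng = np.random.default_rng(2)
        draws = {f"beta_{p}_{c}": np.zeros((1, 400))
                 for p in "abcdefgh" for c in ("Intercept", "SP", "tP", "Start")}
        for p, v in dict(a=5, b=0, c=4, d=1, e=11, f=2, g=5, h=1).items():
            draws[f"beta_{p}_Intercept"] += v
        draws["beta_c_tP"] += diff
        return PosteriorDraws(draws)

    def test_constant_difference_certain(self):
        draws = self.constant_diff_draws(1.0)
        res = treatment_contrast(draws, ("tP", "PEI"), [16], delta=0.4)
        # at T16 the logistic sits essentially at its ceiling c
        assert res["p_superior"] == 1.0

    def test_identical_treatments_equivalent(self):
        draws = self.constant_diff_draws(0.0)
        res = treatment_contrast(draws, ("tP", "PEI"), range(7, 17), delta=0.4)
        assert res["mean_difference"] == 0.0
        assert res["p_equivalent"] == 1.0

    def test_normal_oracle(self):
        rng = np.random.default_rng(3)
        draws = self.constant_diff_draws(0.0)
        noise = rng.normal(0.5, 0.25, (1, 400))
        draws.draws["beta_c_tP"] = noise
        res = treatment_contrast(draws, ("tP", "PEI"), [16], delta=0.4)
        expected = 1 - stats.norm.cdf((0.4 - 0.5) / 0.25)
        assert res["p_superior"] == pytest.approx(expected, abs=0.06)

    def test_p_superior_monotone_in_delta(self):
        draws = self.constant_diff_draws(0.0)
        draws.draws["beta_c_tP"] = np.random.default_rng(4).normal(
            0.5, 0.3, (1, 400))
        ps = [treatment_contrast(draws, ("tP", "PEI"), [16], d)["p_superior"]
              for d in (0.1, 0.3, 0.5, 0.8)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestDose:
    def test_onset_dose_zero(self):
        assert dose_at(6, 2.0).dose == 0.0

    def test_end_of_online(self):
        assert dose_at(16, 2.0).dose == pytest.approx(40.0)

    def test_composed_minimum_effective_dose(self):
        dmin, _ = dmin_dmax(4, 2, 1, 11, 0.4)
        dv = dose_at(dmin, 2.0)
        assert dv.dose == pytest.approx(2 * 2 * (11 - math.log(4) - 6))

    def test_linear_in_intensity_and_time(self):
        tl = StimulationTimeline()
        assert dose_at(10, 4.0, tl).dose == 2 * dose_at(10, 2.0, tl).dose
        assert dose_at(14, 2.0, tl).dose == 2 * dose_at(10, 2.0, tl).dose

    def test_pre_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            dose_at(4, 2.0)

    def test_effective_dose_pair(self):
        low, high = effective_doses(4, 2, 1, 11, 0.4)
        assert low.dose < high.dose
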