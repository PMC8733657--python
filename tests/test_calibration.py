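"""Clearance fitting, sensitivity sweeps, allometric scaling, and the
dissolution-rate experiment."""

import numpy as np
import pytest

import cefapbpk as cp
from cefapbpk.calibration import (
    allometric_fit,
    compare_release_rates,
    fit_clearance,
    psa_sweep,
)
from cefapbpk.params import ParameterError
from cefapbpk.synthetic import NoiseModel, RAT_SCHEDULE_H, generate_observed_profile


class TestFitClearance:
    @pytest.mark.parametrize("species, dose", [("mouse", 4.79), ("rat", 0.62),
                                               ("human", 375.5)])
    def test_noiseless_recovery(self, species, dose):
        model = cp.build_model(species)
        obs = generate_observed_profile(
            model, None, cp.DoseEvent("iv_bolus", dose),
            np.linspace(0.25, 8.0, 8), NoiseModel(cv=0.0),
        )
        fit = fit_clearance(obs, model, cp.DoseEvent("iv_bolus", dose))
        assert not fit.at_bound
        assert fit.clearance == pytest.approx(model.drug.renal_clearance, rel=0.01)

    def test_bounds_excluding_truth_flagged(self, rat_model):
        obs = generate_observed_profile(
            rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
            RAT_SCHEDULE_H, NoiseModel(cv=0.0),
        )
        fit = fit_clearance(obs, rat_model, cp.DoseEvent("iv_bolus", 0.62),
                            bounds=(1.0, 10.0))
        assert fit.at_bound

    def test_noisy_recovery_seed_pinned(self, rat_model):
        obs = generate_observed_profile(
            rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
            np.linspace(0.25, 6.0, 9), NoiseModel(cv=0.1, seed=20210623),
        )
        fit = fit_clearance(obs, rat_model, cp.DoseEvent("iv_bolus", 0.62))
        assert fit.clearance == pytest.approx(0.18, rel=0.10)

    def test_too_few_points_rejected(self, rat_model):
        obs = cp.ObservedProfile(np.array([1.0, 2.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match=">= 4"):
            fit_clearance(obs, rat_model, cp.DoseEvent("iv_bolus", 0.62))


class TestPsaSweep:
    def test_cl_sweep_auc_exactly_reciprocal(self, rat_model):
        factors = [0.1, 0.5, 1.0, 2.0, 10.0]
        res = psa_sweep(rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
                        "cl_renal", factors=factors, t_end=24.0)
        baseline = res.auc_0_inf[factors.index(1.0)]
        assert np.allclose(res.auc_0_inf, baseline / np.array(factors), rtol=5e-3)

    def test_factor_one_is_baseline(self, rat_model, rat_iv_result):
        res = psa_sweep(rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
                        "kp:kidney", factors=[1.0], t_end=24.0)
        m = cp.pk_metrics(rat_iv_result)
        assert res.auc_0_inf[0] == pytest.approx(m.auc_0_inf, rel=1e-6)
        assert res.cmax[0] == pytest.approx(m.cmax, rel=1e-6)

    @pytest.mark.parametrize("tissue", ["muscle", "kidney"])
    def test_kp_sweep_leaves_iv_auc_unchanged(self, rat_model, tissue):
        """Distribution does not change total exposure in a linear model."""
        res = psa_sweep(rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
                        f"kp:{tissue}", factors=[0.1, 1.0, 10.0], t_end=24.0)
        assert np.allclose(res.auc_0_inf, res.auc_0_inf[1], rtol=5e-3)

    def test_solubility_sweep_insensitive_oral(self, human_model, human_gut,
                                               oral_dose):
        res = psa_sweep(human_model, human_gut, oral_dose, "solubility",
                        factors=[0.1, 1.0, 10.0])
        assert np.all(
            np.abs(res.auc_0_inf / res.auc_0_inf[1] - 1.0) < 0.01
        )

    def test_unknown_parameter_rejected(self, rat_model):
        with pytest.raises(ParameterError, match="unknown"):
            psa_sweep(rat_model, None, cp.DoseEvent("iv_bolus", 0.62),
                      "banana", factors=[1.0])


class TestAllometry:
    BW = (0.025, 0.31, 75.1)

    def test_vss_power_law_constants(self):
        fit = allometric_fit((0.012, 0.159, 24.747), self.BW)
        assert fit.coefficient_a == pytest.approx(0.4288, rel=5e-3)
        assert fit.exponent_b == pytest.approx(0.9476, rel=5e-3)
        assert fit.r_squared == pytest.approx(0.9993, abs=5e-4)

    def test_cl_power_law_constants(self):
        fit = allometric_fit((0.031, 0.18, 8.50), self.BW)
        assert fit.coefficient_a == pytest.approx(0.4108, rel=5e-3)
        assert fit.exponent_b == pytest.approx(0.7012, rel=5e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-4)

    def test_exact_power_law_recovered(self):
        bw = np.array([0.02, 1.0, 70.0])
        fit = allometric_fit(2.0 * bw**0.75, bw)
        assert fit.coefficient_a == pytest.approx(2.0, rel=1e-9)
        assert fit.exponent_b == pytest.approx(0.75, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        y = np.array([0.012, 0.159, 24.747])
        base = allometric_fit(y, self.BW)
        scaled = allometric_fit(7.0 * y, self.BW)
        assert scaled.coefficient_a == pytest.approx(7 * base.coefficient_a,
                                                     rel=1e-9)
        assert scaled.exponent_b == pytest.approx(base.exponent_b, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            allometric_fit((0.0, 1.0, 2.0), self.BW)


class TestReleaseRates:
    def test_reference_has_zero_error(self, comparison):
        i = list(comparison.t85_grid).index(0.5)
        assert comparison.cmax_error_pct[i] == 0.0
        assert comparison.auc_error_pct[i] == 0.0

    def test_errors_grow_monotonically_with_t85(self, comparison):
        assert np.all(np.diff(comparison.cmax_error_pct) >= 0)
        assert np.all(np.diff(comparison.auc_error_pct) >= 0)

    def test_slowest_release_degrades_most(self, comparison):
        i2 = list(comparison.t85_grid).index(2.0)
        i6 = list(comparison.t85_grid).index(6.0)
        assert comparison.cmax_error_pct[i6] > comparison.cmax_error_pct[i2]
        assert comparison.auc_error_pct[i6] > comparison.auc_error_pct[i2]

    def test_missing_reference_rejected(self, human_model, human_gut, oral_dose):
        with pytest.raises(ValueError, match="reference"):
            compare_release_rates(human_model, human_gut, oral_dose,
                                  t85_grid=[1.0, 2.0])
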