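"""Gut transit/absorption model: elementary rate laws, conservation,
fraction absorbed, and the transporter calibration."""

import numpy as np
import pytest

import cefapbpk as cp
from cefapbpk.gut import (
    DissolutionSpec,
    GutSegment,
    IDX_ABSORBED,
    IDX_EXCRETED,
    N_SEG,
    TransporterKinetics,
    build_gut_rhs,
    calibrate_transporter_scale,
    compute_fa,
    dissolution_transfer,
    gut_initial_state,
    passive_absorption_rate,
    transporter_flux,
)
from cefapbpk.params import ParameterError


@pytest.fixture
def duodenum():
    return GutSegment(
        name="duodenum", transit_time=0.26, radius=1.6, length=15.0,
        fluid_volume=48.25, pept1_expression=16.28, passive_scale=1.0,
    )


@pytest.fixture
def kinetics():
    return TransporterKinetics(km=860.31, vmax_per_expression=0.0025,
                               global_scale=1.0)


class TestTransporterFlux:
    def test_half_saturation_at_km(self, duodenum, kinetics):
        plateau = 1.0 * 0.0025 * 16.28 * 3600 / 1000  # mg/h
        flux = transporter_flux(860.31, duodenum, kinetics)
        assert flux == pytest.approx(plateau / 2, rel=1e-12)

    def test_zero_concentration_zero_flux(self, duodenum, kinetics):
        assert transporter_flux(0.0, duodenum, kinetics) == 0.0

    def test_saturation_plateau(self, duodenum, kinetics):
        plateau = 0.0025 * 16.28 * 3.6
        assert transporter_flux(1e12, duodenum, kinetics) == pytest.approx(
            plateau, rel=1e-3
        )

    def test_negative_concentration_rejected(self, duodenum, kinetics):
        with pytest.raises(ValueError):
            transporter_flux(-1.0, duodenum, kinetics)

    def test_scales_with_expression_and_global_scale(self, duodenum, kinetics):
        base = transporter_flux(100.0, duodenum, kinetics)
        doubled = transporter_flux(
            100.0, duodenum,
            TransporterKinetics(km=860.31, vmax_per_expression=0.0025,
                                global_scale=2.0),
        )
        assert doubled == pytest.approx(2 * base, rel=1e-12)


class TestPassiveRate:
    def test_rate_constant_arithmetic(self, duodenum):
        # ka = 2 * 3e-6 cm/s / 1.6 cm * 3600 = 0.0135 / h
        rate = passive_absorption_rate(1.0, duodenum, peff=0.03e-4)
        assert rate == pytest.approx(0.0135, rel=1e-3)

    def test_zero_peff(self, duodenum):
        assert passive_absorption_rate(5.0, duodenum, peff=0.0) == 0.0

    def test_radius_inverse_proportionality(self, duodenum):
        wide = GutSegment(
            name="duodenum", transit_time=0.26, radius=3.2, length=15.0,
            fluid_volume=48.25, pept1_expression=16.28, passive_scale=1.0,
        )
        assert passive_absorption_rate(1.0, wide, 0.03e-4) == pytest.approx(
            passive_absorption_rate(1.0, duodenum, 0.03e-4) / 2, rel=1e-12
        )


class TestDissolution:
    def test_t85_rate_constant(self):
        spec = DissolutionSpec("first_order", t85=2.0)
        assert spec.rate_constant == pytest.approx(np.log(1 / 0.15) / 2, rel=1e-12)
        assert spec.rate_constant == pytest.approx(0.9486, rel=1e-3)

    def test_zero_undissolved(self):
        spec = DissolutionSpec("first_order", t85=2.0)
        assert dissolution_transfer(0.0, 0.0, spec, 12.44) == 0.0

    def test_saturation_gate_closes(self):
        spec = DissolutionSpec("first_order", t85=2.0)
        assert dissolution_transfer(10.0, 12.44 * 1000, spec, 12.44) == 0.0

    def test_missing_t85_rejected(self):
        with pytest.raises(ParameterError):
            DissolutionSpec("first_order", t85=None)


class TestGutDynamics:
    def test_no_absorption_routes_everything_to_faeces(self, human_model):
        from dataclasses import replace

        drug = replace(human_model.drug, passive_peff=0.0)
        gut = cp.load_human_gut(drug, pept1_enabled=False)
        model = cp.DispositionModel(human_model.physiology, drug)
        res = cp.simulate(model, gut, cp.DoseEvent("oral", 100.0), t_end=200.0)
        g = res.gut_states
        assert compute_fa(res) == pytest.approx(0.0, abs=1e-6)
        assert g[-1, IDX_EXCRETED] == pytest.approx(100.0, rel=1e-3)

    def test_gut_mass_conservation(self, human_oral_result):
        g = human_oral_result.gut_states
        total = g[:, : 2 * N_SEG].sum(axis=1) + g[:, IDX_ABSORBED] + g[:, IDX_EXCRETED]
        assert np.max(np.abs(total - 1126.5)) / 1126.5 < 1e-3

    def test_linear_limit_fa_dose_independent(self, human_model, human_gut):
        """Far below Km the carrier is linear, so Fa is dose-independent."""
        fas = []
        for dose in (0.5, 5.0):
            res = cp.simulate(
                human_model, human_gut, cp.DoseEvent("oral", dose), t_end=48.0
            )
            fas.append(compute_fa(res))
        assert fas[0] == pytest.approx(fas[1], rel=1e-3)

    def test_fa_monotone_in_scale_and_peff(self, human_model, human_gut, oral_dose):
        from dataclasses import replace

        fa = lambda g, m: compute_fa(cp.simulate(m, g, oral_dose, t_end=48.0))
        base = fa(human_gut.with_scale(50.0), human_model)
        assert fa(human_gut.with_scale(100.0), human_model) >= base
        drug_hi = replace(human_model.drug, passive_peff=10 * 0.03e-4)
        model_hi = cp.DispositionModel(human_model.physiology, drug_hi)
        gut_hi = replace(human_gut.with_scale(50.0), drug=drug_hi)
        assert fa(gut_hi, model_hi) >= base

    def test_instant_vs_fast_first_order_agree(self, human_model, human_gut,
                                               oral_dose):
        """When dissolution is much faster than transit it is not
        rate-limiting: T85% = 0.05 h reproduces instant-release Fa."""
        fast = human_gut.with_dissolution(DissolutionSpec("first_order", t85=0.05))
        fa_fast = compute_fa(cp.simulate(human_model, fast, oral_dose, t_end=48.0))
        fa_instant = compute_fa(
            cp.simulate(human_model, human_gut, oral_dose, t_end=48.0)
        )
        assert fa_fast == pytest.approx(fa_instant, abs=5e-3)

    def test_compute_fa_rejects_iv(self, rat_iv_result):
        with pytest.raises(ValueError):
            compute_fa(rat_iv_result)


class TestCalibration:
    def test_fixed_point_reproduces_bundled_scale(self, human_model, human_gut,
                                                  oral_dose):
        """Re-running the calibration must land on the bundled global_scale
        and reproduce Fa = 0.999."""
        scale = calibrate_transporter_scale(
            human_model, human_gut, oral_dose, target_fa=0.999
        )
        assert scale == pytest.approx(human_gut.kinetics.global_scale, rel=0.02)
        res = cp.simulate(
            human_model, human_gut.with_scale(scale), oral_dose, t_end=48.0
        )
        assert compute_fa(res) == pytest.approx(0.999, abs=0.005)

    def test_unreachable_target_rejected(self, human_model, human_gut, oral_dose):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_transporter_scale(
                human_model, human_gut, oral_dose, target_fa=0.999,
                bracket=(0.0, 1.0),
            )

    def test_target_below_passive_floor_rejected(self, human_model, human_gut,
                                                 oral_dose):
        with pytest.raises(ValueError, match="passive-only"):
            calibrate_transporter_scale(
                human_model, human_gut, oral_dose, target_fa=0.01
            )
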