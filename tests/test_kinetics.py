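"""Closed-form kinetics against independently computed reference values.

Reference values were computed by direct high-precision evaluation of
the printed expressions (Boltzmann splitting, harmonic rate sums,
flux-difference velocity, biased-hopping slip terms) with the Kip3
parameter set, independent of the implementation under test.
"""

import math

import numpy as np
import pytest

import kip3slip as ks
from kip3slip import Condition, MotorParameters, ZeroATPError


class TestBindingProbability:
    def test_unloaded_kip3(self, kip3):
        # exp(1.1) / (exp(1.1) + 1)
        assert ks.binding_probability(kip3, 0.0) == pytest.approx(0.7502601055951176, rel=1e-9)

    def test_zero_docking_energy_is_symmetric(self, kip3):
        params = kip3.replace(E_NL=0.0)
        assert ks.binding_probability(params, 0.0) == 0.5

    @pytest.mark.parametrize("F", [50.0, 1e3])
    def test_large_forward_load_saturates_to_one(self, kip3, F):
        p = ks.binding_probability(kip3, F)
        assert 0.999 < p <= 1.0 and math.isfinite(p)

    @pytest.mark.parametrize("F", [-50.0, -1e3])
    def test_large_backward_load_vanishes_without_overflow(self, kip3, F):
        p = ks.binding_probability(kip3, F)
        assert 0.0 <= p < 1e-3 and math.isfinite(p)


class TestAtpaseRates:
    def test_saturating_unloaded(self, kip3, unloaded_sat):
        k_T, k_L = ks.atpase_rates(kip3, unloaded_sat)
        assert k_T == pytest.approx(21.7136, rel=1e-4)
        assert k_L == pytest.approx(41.5859, rel=1e-4)

    def test_finite_atp_unloaded(self, kip3):
        k_T, k_L = ks.atpase_rates(kip3, Condition(0.0, atp=10.0))
        assert k_T == pytest.approx(6.8460, rel=1e-4)
        assert k_L == pytest.approx(8.0588, rel=1e-4)

    def test_high_atp_converges_to_saturating(self, kip3, unloaded_sat):
        sat = ks.atpase_rates(kip3, unloaded_sat)
        big = ks.atpase_rates(kip3, Condition(0.0, atp=1e9))
        assert big == pytest.approx(sat, rel=1e-3)

    def test_zero_atp_raises(self, kip3):
        with pytest.raises(ZeroATPError):
            ks.atpase_rates(kip3, Condition(0.0, atp=0.0))

    def test_total_rate_is_sum(self, kip3, unloaded_sat):
        k_T, k_L = ks.atpase_rates(kip3, unloaded_sat)
        assert ks.total_atpase_rate(kip3, unloaded_sat) == k_T + k_L
        assert ks.total_atpase_rate(kip3, unloaded_sat) == pytest.approx(63.2995, rel=1e-4)
        assert ks.total_atpase_rate(kip3, Condition(0.0, 10.0)) == pytest.approx(14.9048, rel=1e-4)


class TestVelocityNoSlip:
    def test_unloaded_saturating(self, kip3, unloaded_sat):
        assert ks.velocity_no_slip(kip3, unloaded_sat) == pytest.approx(47.2413, rel=1e-4)

    def test_vanishes_at_stall(self, kip3):
        F_S = ks.stall_force(kip3)
        assert abs(ks.velocity_no_slip(kip3, Condition.saturating(-F_S))) < 1e-6

    def test_unloaded_10uM(self, kip3):
        assert ks.velocity_no_slip(kip3, Condition(0.0, 10.0)) == pytest.approx(24.9894, rel=1e-4)


class TestVelocitySimpleForm:
    CAPTION = dict(r0=1.5, F_S=1.1, k_plus=23.0, k_minus=2.3 * 23.0)

    def test_unloaded(self):
        v = ks.velocity_no_slip_simple(F=0.0, **self.CAPTION)
        assert v == pytest.approx(47.5506, rel=1e-4)

    def test_stalls_at_minus_F_S(self):
        assert ks.velocity_no_slip_simple(F=-1.1, **self.CAPTION) == pytest.approx(0.0, abs=1e-12)

    def test_forward_asymptote_k_plus_d(self):
        v = ks.velocity_no_slip_simple(F=100.0, **self.CAPTION)
        assert v == pytest.approx(23.0 * 8.0, rel=1e-3)

    def test_invalid_r0_rejected(self):
        with pytest.raises(ValueError):
            ks.velocity_no_slip_simple(r0=1.0, F_S=1.1, k_plus=23, k_minus=45, F=0.0)


class TestPeriod2:
    def test_probability_unloaded(self, kip3):
        # 0.75026*22/422 + 0.24974*45/445
        assert ks.period2_probability(kip3, 0.0) == pytest.approx(0.064368, rel=1e-4)

    def test_fast_adp_release_suppresses_period2(self, kip3):
        assert ks.period2_probability(kip3.replace(k_D=1e9), 0.0) < 1e-6

    def test_slow_adp_release_forces_period2(self, kip3):
        assert ks.period2_probability(kip3.replace(k_D=1e-9), 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_fraction_equals_probability_at_saturating(self, kip3):
        for F in np.linspace(-2, 2, 9):
            assert ks.period2_fraction(kip3, Condition.saturating(F)) == ks.period2_probability(kip3, F)

    def test_fraction_finite_atp(self, kip3):
        # 0.75026*(1/400)/(1/10+1/22+1/400) + 0.24974*(1/400)/(1/10+1/45+1/400)
        assert ks.period2_fraction(kip3, Condition(0.0, 10.0)) == pytest.approx(0.0176831, rel=1e-4)

    def test_fraction_converges_to_saturating(self, kip3):
        sat = ks.period2_fraction(kip3, Condition.saturating(0.0))
        assert ks.period2_fraction(kip3, Condition(0.0, 1e9)) == pytest.approx(sat, rel=1e-3)


class TestSlipVelocity:
    def test_zero_at_no_load(self, kip3):
        assert ks.slip_velocity(kip3, 0.0) == 0.0

    def test_one_piconewton(self, kip3):
        # 45*(e^{4/4.1} - e^{-4/4.1})*8
        assert ks.slip_velocity(kip3, 1.0) == pytest.approx(819.2959, rel=1e-4)

    def test_odd_symmetry(self, kip3):
        assert ks.slip_velocity(kip3, -1.0) == pytest.approx(-ks.slip_velocity(kip3, 1.0), rel=1e-12)


class TestTotalVelocity:
    def test_no_slip_contribution_at_zero_load(self, kip3, unloaded_sat):
        res = ks.total_velocity(kip3, unloaded_sat)
        assert res.v_slip == 0.0
        assert res.v_total == res.v0

    def test_slip_term_composition_backward_load(self, kip3):
        cond = Condition.saturating(-1.0)
        res = ks.total_velocity(kip3, cond)
        expected_slip = (
            ks.period2_probability(kip3, -1.0)
            * ks.period2_fraction(kip3, cond)
            * ks.slip_velocity(kip3, -1.0)
        )
        assert res.v_slip == pytest.approx(expected_slip, rel=1e-12)
        assert res.v_total == res.v0 + res.v_slip

    def test_no_hopping_degenerates_to_walking(self, kip3):
        quiet = kip3.replace(v_II0=0.0)
        for F in (-2.0, -0.5, 0.7, 3.0):
            cond = Condition.saturating(F)
            res = ks.total_velocity(quiet, cond)
            assert res.v_total == ks.velocity_no_slip(quiet, cond)

    def test_breakdown_consistency(self, kip3):
        bd = ks.total_velocity(kip3, Condition(-0.5, 100.0)).breakdown
        assert bd.k_total == bd.k_T + bd.k_L
        assert 0 <= bd.P_E <= 1 and 0 <= bd.P_II <= 1 and 0 <= bd.F_II <= 1


class TestSlippingTime:
    def test_saturating_limit_is_adp_release_time(self, kip3):
        assert ks.slipping_time(kip3) == pytest.approx(2.5e-3, rel=1e-12)

    def test_one_millimolar_atp(self, kip3):
        assert ks.slipping_time(kip3, atp=1000.0) == pytest.approx(3.5e-3, rel=1e-9)

    def test_adp_inert_when_binding_rate_zero(self, kip3):
        assert ks.slipping_time(kip3, atp=1000.0, adp=1000.0) == ks.slipping_time(kip3, atp=1000.0)

    def test_adp_slows_rebinding_when_it_competes(self, kip3):
        competing = kip3.replace(k_bD=0.5)
        assert ks.slipping_time(competing, atp=10.0, adp=1000.0) > ks.slipping_time(competing, atp=10.0)

    def test_no_atp_diverges(self, kip3):
        with pytest.raises(ZeroATPError):
            ks.slipping_time(kip3, atp=0.0)


class TestSteppingRatios:
    def test_no_slip_unloaded(self, kip3):
        assert ks.stepping_ratio_no_slip(kip3, 0.0) == pytest.approx(1.56859, rel=1e-4)

    def test_with_slip_unloaded(self, kip3):
        assert ks.stepping_ratio_with_slip(kip3, 0.0) == pytest.approx(1.55856, rel=1e-4)

    def test_both_near_1p6_unloaded(self, kip3):
        assert ks.stepping_ratio_no_slip(kip3, 0.0) == pytest.approx(1.6, abs=0.05)
        assert ks.stepping_ratio_with_slip(kip3, 0.0) == pytest.approx(1.6, abs=0.05)

    def test_unity_at_stall(self, kip3):
        F_S = ks.stall_force(kip3)
        assert ks.stepping_ratio_no_slip(kip3, -F_S) == pytest.approx(1.0, abs=1e-6)

    def test_infinite_sentinel_when_front_binding_certain(self, kip3):
        assert ks.stepping_ratio_no_slip(kip3.replace(E_NL=2000.0), 0.0) == math.inf

    def test_no_hopping_collapses_with_slip_to_no_slip(self, kip3):
        quiet = kip3.replace(v_II0=0.0)
        for F in np.linspace(-2, 2, 9):
            assert ks.stepping_ratio_with_slip(quiet, F) == ks.stepping_ratio_no_slip(quiet, F)

    def test_adp_only_unloaded_is_unity(self, kip3):
        assert ks.stepping_ratio_adp_only(kip3, 0.0) == 1.0

    def test_adp_only_one_piconewton(self, kip3):
        # e^{2*4/4.1}
        assert ks.stepping_ratio_adp_only(kip3, 1.0) == pytest.approx(7.0373, rel=1e-4)

    def test_adp_only_antisymmetry(self, kip3):
        for F in (0.3, 1.0, 2.5):
            product = ks.stepping_ratio_adp_only(kip3, F) * ks.stepping_ratio_adp_only(kip3, -F)
            assert product == pytest.approx(1.0, rel=1e-12)

    def test_overflow_returns_sentinels(self, kip3):
        assert ks.stepping_ratio_adp_only(kip3, 1e3) == math.inf
        assert ks.stepping_ratio_adp_only(kip3, -1e3) == 0.0
        assert ks.stepping_ratio_with_slip(kip3, 1e3) == math.inf


class TestStallForce:
    def test_full_model_root(self, kip3):
        assert ks.stall_force(kip3) == pytest.approx(1.05059, abs=1e-4)

    def test_matches_printed_scale_about_one_piconewton(self, kip3):
        assert ks.stall_force(kip3) == pytest.approx(1.0, abs=0.15)

    def test_closed_form_seed(self, kip3):
        expected = 4.1 * (1.1 - math.log(45.0 / 22.0)) / 1.7
        assert ks.stall_force_closed_form(kip3) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.92703, rel=1e-4)

    def test_with_slip_stall_smaller_than_no_slip(self, kip3):
        # Under backward load the slip term is backward, so the total
        # velocity stalls at a smaller backward load than the walk alone.
        with_slip = ks.stall_force(kip3, include_slip=True)
        assert with_slip == pytest.approx(0.9745, abs=1e-3)
        assert with_slip < ks.stall_force(kip3)

    def test_backward_biased_motor_has_no_stall(self, kip3):
        backwards = kip3.replace(E_NL=0.0, k_plus=1.0)
        with pytest.raises(ValueError):
            ks.stall_force(backwards)


class TestSlipDiffusion:
    def test_kip3_value(self, kip3):
        assert ks.slip_diffusion_constant(kip3) == 45.0 * 64.0 / 2.0 == 1440.0

    def test_no_hopping_no_diffusion(self, kip3):
        assert ks.slip_diffusion_constant(kip3.replace(v_II0=0.0)) == 0.0

    def test_linear_in_hop_rate(self, kip3):
        assert ks.slip_diffusion_constant(kip3.replace(v_II0=90.0)) == 2 * ks.slip_diffusion_constant(kip3)


class TestParameters:
    def test_preset_is_table_values(self, kip3):
        assert (kip3.k_D, kip3.k_plus, kip3.k_minus) == (400.0, 22.0, 45.0)
        assert (kip3.E_NL, kip3.d_plus, kip3.v_II0, kip3.k_bT) == (1.1, 1.7, 45.0, 1.0)
        assert kip3.d_minus == kip3.d_plus
        assert kip3.d == 8.0 and kip3.delta == 4.0

    def test_delta_not_independently_settable(self, kip3):
        with pytest.raises(ValueError):
            MotorParameters.from_dict({**kip3.to_dict(), "delta": 3.0})
        # A consistent delta in a config file is accepted.
        again = MotorParameters.from_dict({**kip3.to_dict(), "delta": 4.0})
        assert again == kip3

    @pytest.mark.parametrize("field,value", [("k_D", 0.0), ("k_plus", -1.0), ("E_NL", -0.1), ("kBT", 0.0)])
    def test_invalid_values_rejected(self, kip3, field, value):
        with pytest.raises(ValueError):
            kip3.replace(**{field: value})

    def test_file_round_trip(self, kip3, tmp_path):
        for name in ("p.json", "p.yaml"):
            path = tmp_path / name
            if name.endswith(".json"):
                import json

                path.write_text(json.dumps(kip3.to_dict()))
            else:
                import yaml

                path.write_text(yaml.safe_dump(kip3.to_dict()))
            assert MotorParameters.from_file(path) == kip3

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition(0.0, atp=-1.0)
        with pytest.raises(ValueError):
            Condition(0.0, atp="plenty")
        assert Condition(0.0, atp="SATURATING").is_saturating
        assert not Condition(0.0, atp=100.0).is_saturating
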