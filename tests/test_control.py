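"""Perturbational control analysis and the summation theorems."""

import math

import numpy as np
import pytest

import innatedyn as idn
from innatedyn.control import (BranchJumpError, control_coefficient,
                               control_profile, control_vs_parameter_scan)


class TestDecayExact:
    def test_influx_and_loss_coefficients_are_plus_minus_one(self, decay_model):
        ss = idn.find_steady_state(decay_model, classify=False)
        c_v = control_coefficient(decay_model, ss, "x", "influx")
        c_k = control_coefficient(decay_model, ss, "x", "decay")
        # x* = v/k: exactly +1 and -1 (log-log derivative of a power law has
        # no curvature, so even a finite step is exact)
        assert c_v.value == pytest.approx(1.0, abs=1e-9)
        assert c_k.value == pytest.approx(-1.0, abs=1e-9)

    def test_profile_sums_to_zero(self, decay_model):
        ss = idn.find_steady_state(decay_model, classify=False)
        _, rep = control_profile(decay_model, ss, "x")
        assert abs(rep.sum_concentration_coeffs) < 1e-6

    def test_coefficients_invariant_under_step_halving(self, decay_model):
        ss = idn.find_steady_state(decay_model, classify=False)
        a = control_coefficient(decay_model, ss, "x", "influx", rel_step=1e-2)
        b = control_coefficient(decay_model, ss, "x", "influx", rel_step=5e-3)
        assert a.value == pytest.approx(b.value, abs=1e-4)


class TestStepLadderOracle:
    def test_switch1d_matches_fine_secant_ladder(self, switch_model):
        # independent oracle: one-sided secant over a 10x finer step
        ss = idn.find_steady_state(switch_model, np.array([0.5]),
                                   classify=False)
        c = control_coefficient(switch_model, ss, "x", "basal_influx",
                                rel_step=1e-4)
        from innatedyn.steadystate import _damped_newton
        s = 1e-5
        vals = []
        for fac in (1.0 + s, 1.0 - s):
            m = switch_model.with_activity("basal_influx", fac)
            y, _, ok = _damped_newton(m, ss.state)
            assert ok
            vals.append(float(y[0]))
        oracle = (math.log(vals[0]) - math.log(vals[1])) / \
                 (math.log(1 + s) - math.log(1 - s))
        assert c.value == pytest.approx(oracle, abs=1e-4)


class TestSummationTheorems:
    def test_toggle2d_concentration_sums_vanish_for_both_species(self,
                                                                 toggle_model):
        ss = idn.find_steady_state(toggle_model, np.array([3.0, 0.1]),
                                   classify=False)
        for target in ("x", "y"):
            _, rep = control_profile(toggle_model, ss, target)
            assert abs(rep.sum_concentration_coeffs) < 1e-3

    def test_flux_control_sums_to_one_on_switch1d(self, switch_model):
        ss = idn.find_steady_state(switch_model, np.array([0.5]),
                                   classify=False)
        _, rep = control_profile(switch_model, ss, "flux:loss")
        assert rep.sum_flux_coeffs == pytest.approx(1.0, abs=1e-3)


class TestInflammationProfiles:
    def test_acute_control_is_distributed_with_mmp7_positive_mmp8_negative(
            self, inflammation_model, acute_state):
        coeffs, rep = control_profile(inflammation_model, acute_state, "TNF",
                                      mode="acute")
        by_tag = {c.parameter: c for c in coeffs}
        assert by_tag["TNF_production"].value == pytest.approx(1.0, abs=0.05)
        assert by_tag["TNF_washout"].value == pytest.approx(-1.0, abs=0.05)
        assert by_tag["MMP7_release"].value > 0.01
        assert by_tag["MMP8_release"].value < -0.1
        assert abs(by_tag["MMP8_release"].value) > by_tag["MMP7_release"].value
        assert by_tag["CRA_influx"].value > 0.1
        # control spread over many processes
        assert sum(abs(c.value) > 0.05 for c in coeffs) >= 8
        assert abs(rep.sum_concentration_coeffs) < 1e-3

    def test_chronic_control_concentrates_in_tnf_turnover_with_ao_flags(
            self, inflammation_model, chronic_state):
        coeffs, rep = control_profile(inflammation_model, chronic_state, "TNF",
                                      mode="chronic")
        by_tag = {c.parameter: c for c in coeffs}
        assert by_tag["TNF_production"].value == pytest.approx(1.0, abs=0.01)
        assert by_tag["TNF_washout"].value == pytest.approx(-1.0, abs=0.01)
        # fibroblast-dependent processes are AO (species below floor)
        for tag in ("MMP7_release", "MMP8_release", "fibroblast_growth",
                    "fibroblast_killing", "CRA_secretion", "CRA_clipoff"):
            assert not by_tag[tag].computable
            assert by_tag[tag].value == 0.0
        assert abs(rep.sum_concentration_coeffs) < 1e-3

    def test_antigen_control_of_tnf_is_bimodal(self, inflammation_model,
                                               acute_state, chronic_state):
        # acute mode: clear positive control by antigen influx; chronic mode
        # at the same load: control near zero (mast cells saturated)
        m = inflammation_model
        c_acute = control_coefficient(m, acute_state, "TNF", "CRA_influx")
        c_chronic = control_coefficient(m, chronic_state, "TNF", "CRA_influx")
        assert c_acute.value > 0.5
        assert abs(c_chronic.value) < 0.1

    def test_acute_sensitivity_grows_toward_threshold(self, inflammation_model):
        m = inflammation_model
        up = idn.branch_scan(m, "v_CRA", [1.0, 4.0, 5.5], m.initial_state(),
                             confirm_horizon=2e3)
        tab = control_vs_parameter_scan(m, up, "TNF", "CRA_influx")
        vals = tab["coefficient"].to_numpy()
        assert np.all(np.diff(vals) > 0), "coefficient must grow toward the fold"
        assert vals[-1] > 2 * vals[0]


class TestBranchJumps:
    def test_jump_guard_raises_close_to_fold(self, switch_model):
        # the low state at default constants sits within 1% (in the loss
        # activity) of its fold: the default step must be refused
        ss = idn.find_steady_state(switch_model, np.array([0.5]),
                                   classify=False)
        with pytest.raises(BranchJumpError):
            control_coefficient(switch_model, ss, "x", "loss", rel_step=1e-2)

    def test_profile_recovers_with_fallback_step(self, switch_model):
        ss = idn.find_steady_state(switch_model, np.array([0.5]),
                                   classify=False)
        coeffs, rep = control_profile(switch_model, ss, "x")
        assert abs(rep.sum_concentration_coeffs) < 1e-3
        loss = [c for c in coeffs if c.parameter == "loss"][0]
        assert loss.rel_step < 1e-2
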