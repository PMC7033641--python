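"""Model construction, structural invariants and the analytic toy fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import innatedyn as idn
from innatedyn.network_model import SWITCH1D_DEFAULTS, switch1d_fixed_points


class TestDefaultModel:
    def test_confluency_ceiling_is_1000_fM(self):
        m = idn.build_default_model()
        assert m.parameters["F_max"] == 1000.0
        assert m.constants["F_max"] == 1000.0

    def test_unknown_override_is_rejected_by_name(self):
        with pytest.raises(idn.ConfigurationError, match="no_such_constant"):
            idn.build_default_model({"no_such_constant": 1.0})

    def test_nonpositive_confluency_is_rejected(self):
        with pytest.raises(idn.ModelValidationError):
            idn.build_default_model({"F_max": 0.0})

    def test_all_zero_state_is_fixed_point_without_cells_or_influxes(self):
        # every production term is proportional to a cell concentration, so
        # emptying the cell pools and influxes makes the origin invariant
        m = idn.build_default_model({
            "v_CRA": 0.0, "v_fibroblast": 0.0, "v_protease": 0.0,
            "B_cells": 0.0, "mast_cells": 0.0,
            "initial:fibroblasts": 0.0, "initial:R_free": 0.0,
        })
        zero = np.zeros(len(m.dynamic_species))
        assert np.allclose(m.rhs(0.0, zero), 0.0)

    def test_receptor_pool_is_conserved_along_trajectory(self):
        # brute-force oracle: integrate 1e4 min from a perturbed state and
        # check free + FLC-loaded + crosslinked receptors stay constant
        m = idn.build_inflammation_model()
        y0 = m.initial_state()
        names = m.dynamic_species
        y0[names.index("TNF")] = 5e4  # well off the steady state
        traj = idn.integrate(m, y0, 1e4,
                             output_grid=np.linspace(0, 1e4, 50))
        total = (traj["R_free"] + traj["R_FLC"] + traj["R_cross"])
        assert np.allclose(total, total[0], rtol=1e-6)

    def test_receptor_cycle_is_detected_as_conserved_moiety(self):
        m = idn.build_inflammation_model()
        C = m.conservation_matrix()
        assert C.shape[0] == 1
        names = m.dynamic_species
        weights = np.zeros(len(names))
        for r in ("R_free", "R_FLC", "R_cross"):
            weights[names.index(r)] = 1.0
        # the conservation row is parallel to the receptor-sum vector
        c = C[0] / np.linalg.norm(C[0])
        assert abs(abs(c @ weights / np.linalg.norm(weights)) - 1.0) < 1e-10

    def test_rates_nonnegative_at_physical_states(self):
        m = idn.build_default_model()
        rng = np.random.default_rng(0)
        caps = {"fibroblasts": m.parameters["F_max"],
                "bacteria": m.parameters["B_capacity"]}
        for _ in range(50):
            state = {}
            for s in m.species:
                hi = caps.get(s.name, 1e4)
                state[s.name] = float(rng.uniform(0, hi))
            rates = m.reaction_rates(state)
            assert np.all(rates >= 0.0)

    def test_process_tags_are_unique(self):
        m = idn.build_default_model()
        tags = [r.process_tag for r in m.reactions]
        assert len(tags) == len(set(tags))

    def test_expected_processes_present(self):
        m = idn.build_default_model()
        tags = {r.process_tag for r in m.reactions}
        required = {
            "CRA_influx", "CRA_secretion", "CRA_clipoff", "FLC_production",
            "MMP7_release", "MMP8_release", "TNF_production", "TNF_washout",
            "fibroblast_growth", "fibroblast_killing", "fibroblast_influx",
            "bacteria_growth", "bacteria_lysis", "protease_production",
            "protease_influx", "peptide_binding",
        }
        assert required <= tags


class TestFreezing:
    def test_freeze_removes_dimension_and_keeps_value_in_rates(self):
        m = idn.build_inflammation_model()
        frozen = idn.freeze_species(m, "fibroblasts", 0.0)
        assert len(frozen.dynamic_species) == len(m.dynamic_species) - 1
        assert "fibroblasts" not in frozen.dynamic_species
        # MMP release vanishes with fibroblasts clamped at zero
        state = frozen.full_state(frozen.initial_state())
        assert frozen.reaction_rate(frozen.reaction("MMP8_release"), state) == 0.0

    def test_freeze_unknown_species_errors(self):
        m = idn.build_default_model()
        with pytest.raises(idn.ConfigurationError):
            idn.freeze_species(m, "unobtainium", 1.0)

    def test_freeze_decay_at_fixed_point_leaves_empty_system(self):
        m = idn.build_toy_model("decay", v=0.5, k=0.1)
        frozen = idn.freeze_species(m, "x", 5.0)
        assert frozen.dynamic_species == []


class TestToyFixtures:
    def test_decay_closed_form(self, decay_model):
        # x* = v/k, eigenvalue -k
        ss = idn.find_steady_state(decay_model)
        assert ss["x"] == pytest.approx(5.0, abs=1e-9)
        assert ss.max_re == pytest.approx(-0.1, rel=1e-6)

    def test_switch1d_default_constants_have_exact_roots(self, switch_model):
        # rate = 1 + 10 x^2/(36+x^2) - x vanishes exactly at 2, 3 and 6
        roots = switch1d_fixed_points(switch_model, x_max=20.0)
        assert roots == pytest.approx([2.0, 3.0, 6.0], abs=1e-8)

    def test_switch1d_root_scan_matches_brute_force_oracle(self):
        # independent oracle: sign changes of the scalar rate on a dense grid
        m = idn.build_toy_model("switch1d", b=0.5)
        f = lambda x: float(m.rhs(0.0, np.array([x]))[0])
        xs = np.linspace(0, 20, 40001)
        vals = np.array([f(x) for x in xs])
        n_sign_changes = int(np.sum(np.diff(np.sign(vals)) != 0))
        assert len(switch1d_fixed_points(m, x_max=20.0)) == n_sign_changes

    def test_toggle2d_symmetric_state_is_fixed_point(self, toggle_model):
        # s solves s(1+s^2) = alpha; by symmetry x = y = s is steady
        s = np.roots([1, 0, 1, -4.0])
        s = float(s[np.isreal(s)].real[0])
        rhs = toggle_model.rhs(0.0, np.array([s, s]))
        assert np.allclose(rhs, 0.0, atol=1e-12)

    def test_unknown_toy_name_lists_fixtures(self):
        with pytest.raises(idn.ConfigurationError, match="decay.*switch1d.*toggle2d"):
            idn.build_toy_model("pendulum")


class TestSerialization:
    def test_default_model_round_trips_through_yaml(self, tmp_path):
        m = idn.build_default_model({"v_CRA": 2.5})
        path = tmp_path / "model.yaml"
        idn.model_to_yaml(m, path)
        m2 = idn.model_from_yaml(path)
        assert m2.parameters == m.parameters
        assert [s.name for s in m2.species] == [s.name for s in m.species]
        y0 = m.initial_state()
        assert np.allclose(m2.rhs(0.0, y0), m.rhs(0.0, y0))

    def test_expression_models_refuse_serialisation(self, toggle_model, tmp_path):
        from innatedyn.serialize import SerializationError
        with pytest.raises(SerializationError):
            idn.model_to_yaml(toggle_model, tmp_path / "nope.yaml")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(v=st.floats(0.0, 10.0), k=st.floats(0.01, 2.0))
def test_decay_fixed_point_matches_closed_form_for_any_rates(v, k):
    m = idn.build_toy_model("decay", v=v, k=k)
    ss = idn.find_steady_state(m, classify=False)
    assert ss["x"] == pytest.approx(v / k, rel=1e-6, abs=1e-9)
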