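"""Branch scans, hysteresis, threshold and wobble-point localisation."""

import numpy as np
import pytest

import innatedyn as idn
from innatedyn.bifurcation import (BranchPoint, NoFlipError, branch_scan,
                                   classify_branch, eigenvalue_trace,
                                   find_wobble_point, heat_map,
                                   locate_threshold)
from innatedyn.network_model import switch1d_fixed_points


class TestClassifyBranch:
    def test_near_confluent_state_is_acute(self, inflammation_model):
        state = {n: 0.0 for n in inflammation_model.dynamic_species}
        state["fibroblasts"] = 999.5
        y = inflammation_model.state_dict_to_vector(state)
        assert classify_branch(inflammation_model, y) == "acute"

    def test_extinct_fibroblasts_high_tnf_is_chronic(self, inflammation_model):
        state = {n: 0.0 for n in inflammation_model.dynamic_species}
        state["fibroblasts"] = 5e-37
        state["TNF"] = 50e3  # 50 pM
        y = inflammation_model.state_dict_to_vector(state)
        assert classify_branch(inflammation_model, y) == "chronic"

    def test_intermediate_state_with_low_tnf_is_indeterminate(
            self, inflammation_model):
        state = {n: 0.0 for n in inflammation_model.dynamic_species}
        state["fibroblasts"] = 400.0
        state["TNF"] = 1e3  # 1 pM
        y = inflammation_model.state_dict_to_vector(state)
        assert classify_branch(inflammation_model, y) == "indeterminate"


def _switch_classifier(state):
    x = float(np.atleast_1d(state)[0])
    return "high" if x > 3.0 else "low"


class TestScans:
    def test_decay_scan_is_single_branch_without_flip(self, decay_model):
        start = idn.find_steady_state(decay_model, classify=False)
        scan = branch_scan(decay_model, "v", [0.5, 1.0, 2.0, 4.0], start,
                           classifier=lambda s: "only",
                           confirm_horizon=1e3)
        assert scan.flip_interval is None
        assert all(p.branch_label == "only" for p in scan.points)

    def test_switch1d_shows_hysteresis_and_decay_does_not(self, switch_model):
        # up/down scans in the basal influx b: the label sequences must
        # differ over the bistable window
        # the bistable window in b is roughly (0.90, 1.02); the grid must
        # sample it for the up and down paths to disagree
        lo = idn.find_steady_state(switch_model.with_parameters(b=0.2),
                                   np.array([0.5]), classify=False)
        values = [0.2, 0.6, 1.0, 1.4, 1.8]
        up = branch_scan(switch_model, "b", values, lo,
                         classifier=_switch_classifier, confirm_horizon=1e3)
        down = branch_scan(switch_model, "b", values[::-1], up.points[-1].steady,
                           classifier=_switch_classifier, confirm_horizon=1e3)
        assert up.flip_interval is not None
        assert up.labels() != down.labels()[::-1]

    def test_eigenvalue_trace_of_decay_is_constant_minus_k(self, decay_model):
        start = idn.find_steady_state(decay_model, classify=False)
        scan = branch_scan(decay_model, "v", [0.5, 1.0, 2.0], start,
                           classifier=lambda s: "only", confirm_horizon=1e3)
        trace = eigenvalue_trace(scan)
        assert np.allclose(trace["max_re_per_min"], -0.1, rtol=1e-6)


class TestThreshold:
    def test_switch1d_fold_matches_root_count_oracle(self, switch_model):
        # oracle: on a dense grid in b, the fold is where the dense root scan
        # loses the low root
        bs = np.linspace(1.0, 2.0, 201)
        b_fold_oracle = None
        for b in bs:
            roots = switch1d_fixed_points(
                switch_model.with_parameters(b=b), x_max=30.0)
            lo_roots = [r for r in roots if r < 3.5]
            if not lo_roots:
                b_fold_oracle = b
                break
        assert b_fold_oracle is not None
        lo_state = idn.find_steady_state(
            switch_model.with_parameters(b=1.0), np.array([0.5]),
            classify=False)
        b_fold = locate_threshold(switch_model, "b", 1.0, 2.0, tol=0.002,
                                  start_state=lo_state,
                                  classifier=_switch_classifier,
                                  confirm_horizon=1e3)
        assert b_fold == pytest.approx(b_fold_oracle, abs=0.01)

    def test_monostable_decay_raises_no_flip(self, decay_model):
        start = idn.find_steady_state(decay_model, classify=False)
        with pytest.raises(NoFlipError):
            locate_threshold(decay_model, "v", 0.5, 2.0,
                             start_state=start,
                             classifier=lambda s: "only",
                             confirm_horizon=1e3)


class TestWobble:
    def test_switch1d_wobble_equals_unstable_point(self, switch_model):
        # in one dimension the basin boundary IS the unstable fixed point
        lo = idn.find_steady_state(switch_model, np.array([0.5]),
                                   classify=False)
        bp = BranchPoint(1.0, lo, "low")
        w = find_wobble_point(switch_model, bp, "x", tol_rel=1e-3,
                              far_bound=10.0, relax_horizon=3e3,
                              classifier=_switch_classifier)
        assert w.wobble_level == pytest.approx(3.0, rel=2e-3)
        assert w.bracket[0] <= 3.0 <= w.bracket[1] or \
            abs(w.wobble_level - 3.0) < 0.01

    def test_toggle2d_boundary_matches_grid_oracle(self, toggle_model):
        # dense-grid oracle along the probed axis: classify relaxation
        # endpoints from (x0, y_s) and find the sign change
        ss = idn.find_steady_state(toggle_model, np.array([3.5, 0.2]),
                                   classify=False)

        def classify(state):
            x, y = np.atleast_1d(state)[:2]
            return "x_high" if x > y else "y_high"

        xs = np.linspace(0.0, ss["x"], 101)
        oracle = None
        for a, b in zip(xs, xs[1:]):
            la = classify(idn.perturb_and_relax(toggle_model, ss.state, "x",
                                                a, 3e3)[1])
            lb = classify(idn.perturb_and_relax(toggle_model, ss.state, "x",
                                                b, 3e3)[1])
            if la != lb:
                oracle = 0.5 * (a + b)
                break
        assert oracle is not None
        bp = BranchPoint(4.0, ss, "x_high")
        w = find_wobble_point(toggle_model, bp, "x", tol_rel=1e-3,
                              far_bound=0.0, relax_horizon=3e3,
                              classifier=classify)
        assert w.wobble_level == pytest.approx(oracle, abs=ss["x"] / 100.0)

    def test_acute_wobble_lies_below_the_unstable_state(self,
                                                        inflammation_model):
        # multi-dimensional effect: reaching the saddle's fibroblast level is
        # not enough, the basin boundary sits strictly below it
        m = inflammation_model.with_parameters(v_CRA=3.0)
        acute = idn.find_steady_state(m, inflammation_model.initial_state(),
                                      classify=False)
        bp = BranchPoint(3.0, acute, "acute")
        w = find_wobble_point(m, bp, "fibroblasts", relax_horizon=5e4,
                              unstable_grid=[150.0, 300.0])
        assert w.feasible
        assert w.unstable_level is not None
        assert w.wobble_level < w.unstable_level

    def test_chronic_wobble_infeasible_at_moderate_load(self,
                                                        inflammation_model):
        # the irrevertibility window: from the chronic state at moderate
        # antigen load no fibroblast implantation can reach the acute basin
        m = inflammation_model.with_parameters(v_CRA=3.0)
        y0 = m.initial_state()
        y0[m.dynamic_species.index("fibroblasts")] = 0.0
        chronic = idn.find_steady_state(m, y0, classify=False)
        bp = BranchPoint(3.0, chronic, "chronic")
        w = find_wobble_point(m, bp, "fibroblasts", relax_horizon=5e4)
        assert not w.feasible


class TestHeatMap:
    def test_1x1_grid_equals_single_steady_state(self, inflammation_model,
                                                 acute_state):
        hm = heat_map(inflammation_model, "v_CRA", [1.0],
                      "v_fibroblast", [0.0], start_mode="acute")
        assert hm.tnf_pM[0, 0] == pytest.approx(acute_state["TNF"] / 1e3,
                                                rel=1e-6)

    def test_matrix_file_has_axis_headers(self, tmp_path, inflammation_model):
        hm = heat_map(inflammation_model, "v_CRA", [0.1, 1.0],
                      "v_fibroblast", [0.0], start_mode="acute")
        path = tmp_path / "hm.txt"
        hm.to_matrix_file(path)
        lines = path.read_text().splitlines()
        assert "v_CRA" in lines[0] and "v_fibroblast" in lines[0]
        assert lines[1].split("\t")[1:] == ["0.1", "1"]
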