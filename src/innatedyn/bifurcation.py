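"""Branch scans, threshold localisation, wobble (basin-boundary) bisection.

All scans follow the carry-state protocol: the steady-state solve at each
parameter value is seeded with the solution at the previous value, which is
what produces hysteresis loops on bistable models. Branch labels come from a
state classifier, never from the scan direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import integrate, perturb_and_relax
from .network_model import NetworkModel
from .steadystate import (CONFIRM_HORIZON, NoSteadyStateError, SteadyStateResult,
                          find_steady_state, find_unstable_state)

__all__ = [
    "BranchPoint", "BranchScan", "WobbleResult", "HeatMap", "NoFlipError",
    "classify_branch", "branch_scan", "locate_threshold", "find_wobble_point",
    "eigenvalue_trace", "heat_map",
]

#: classifier thresholds (see classify_branch)
ACUTE_FIBROBLAST_FRACTION = 0.5
CHRONIC_FIBROBLAST_FM = 1.0
CHRONIC_TNF_FM = 10_000.0  # 10 pM

#: default confirmation horizon used inside scans (min); shorter than the
#: stand-alone default because scans re-confirm many points
SCAN_CONFIRM_HORIZON = 2e4


class NoFlipError(RuntimeError):
    """Both bracket ends carry the same branch label."""


def classify_branch(model: NetworkModel, state) -> str:
    """Label a steady state acute / chronic / indeterminate.

    Fibroblasts are the primary discriminator (the TNF curves of the two
    branches cross, fibroblast levels never do): acute when fibroblasts reach
    at least half the confluency ceiling, chronic when they are essentially
    extinct (< 1 fM). In the intermediate range TNF breaks the tie (chronic
    above 10 pM), otherwise the state is indeterminate.
    """
    if isinstance(state, SteadyStateResult):
        state = state.state
    names = model.dynamic_species
    try:
        fibro = float(np.asarray(state)[names.index("fibroblasts")])
        tnf = float(np.asarray(state)[names.index("TNF")])
    except ValueError:
        return "indeterminate"
    f_max = model.parameters.get("F_max", model.constants.get("F_max", 1000.0))
    if fibro >= ACUTE_FIBROBLAST_FRACTION * f_max:
        return "acute"
    if fibro < CHRONIC_FIBROBLAST_FM:
        return "chronic"
    if tnf > CHRONIC_TNF_FM:
        return "chronic"
    return "indeterminate"


@dataclass
class BranchPoint:
    parameter_value: float
    steady: SteadyStateResult | None
    branch_label: str  # acute / chronic / indeterminate / failed


@dataclass
class BranchScan:
    parameter_name: str
    direction: str  # up / down
    points: list[BranchPoint]
    flip_interval: tuple[float, float] | None = None
    carry_state: bool = True

    def labels(self) -> list[str]:
        return [p.branch_label for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            tnf = p.steady["TNF"] / 1e3 if (
                p.steady is not None and "TNF" in p.steady.species_names) else np.nan
            fib = p.steady["fibroblasts"] if (
                p.steady is not None and "fibroblasts" in p.steady.species_names
            ) else np.nan
            rows.append((p.parameter_value, p.branch_label,
                         p.steady.max_re if p.steady else np.nan, tnf, fib,
                         p.steady.label if p.steady else "failed"))
        return pd.DataFrame(rows, columns=[
            self.parameter_name, "branch", "max_re_per_min", "TNF_pM",
            "fibroblasts_fM", "stability"])


def branch_scan(model: NetworkModel, parameter: str,
                values: Sequence[float], start_state,
                classifier: Callable | None = None,
                confirm_horizon: float = SCAN_CONFIRM_HORIZON) -> BranchScan:
    """Carry-state scan of a bifurcation parameter.

    ``values`` must be monotone (ascending or descending); ``start_state``
    seeds the solve at ``values[0]``. A failed steady-state solve marks the
    point and the scan continues from the last good state.
    """
    values = list(values)
    if len(values) >= 2 and values[1] < values[0]:
        direction = "down"
        if any(values[i] < values[i + 1] for i in range(len(values) - 1)):
            raise ValueError("values must be monotone")
    else:
        direction = "up"
        if any(values[i] > values[i + 1] for i in range(len(values) - 1)):
            raise ValueError("values must be monotone")
    classify = classifier or (lambda st: classify_branch(model, st))

    points: list[BranchPoint] = []
    carry = np.asarray(
        start_state.state if isinstance(start_state, SteadyStateResult)
        else start_state, dtype=float)
    for v in values:
        m = model.with_parameters(**{parameter: v})
        try:
            ss = find_steady_state(m, carry, confirm_horizon=confirm_horizon)
            label = classify(ss.state)
            points.append(BranchPoint(v, ss, label))
            carry = ss.state
        except (NoSteadyStateError, RuntimeError) as exc:  # point failed
            points.append(BranchPoint(v, None, "failed"))
    flip = None
    labelled = [(p.parameter_value, p.branch_label) for p in points
                if p.branch_label not in ("failed",)]
    for (v0, l0), (v1, l1) in zip(labelled, labelled[1:]):
        if l0 != l1:
            flip = (v0, v1)
            break
    return BranchScan(parameter, direction, points, flip_interval=flip)


def locate_threshold(model: NetworkModel, parameter: str,
                     lo: float, hi: float, tol: float = 0.01,
                     start_state=None,
                     classifier: Callable | None = None,
                     confirm_horizon: float = SCAN_CONFIRM_HORIZON) -> float:
    """Bisect the carry-state up-scan flip between ``lo`` and ``hi``.

    The labels at the two ends must differ (:class:`NoFlipError` otherwise);
    returns the midpoint of the final bracket of width <= ``tol``.
    """
    classify = classifier or (lambda st: classify_branch(model, st))

    def solve(value, seed):
        m = model.with_parameters(**{parameter: value})
        ss = find_steady_state(m, seed, confirm_horizon=confirm_horizon)
        return ss

    seed = (start_state.state if isinstance(start_state, SteadyStateResult)
            else start_state)
    if seed is None:
        seed = model.with_parameters(**{parameter: lo}).initial_state()
    ss_lo = solve(lo, seed)
    lab_lo = classify(ss_lo.state)
    ss_hi = solve(hi, ss_lo.state)
    lab_hi = classify(ss_hi.state)
    if lab_lo == lab_hi:
        raise NoFlipError(
            f"no flip: label {lab_lo!r} at both {parameter}={lo} and {hi}")
    state_lo = ss_lo.state
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ss_mid = solve(mid, state_lo)
        if classify(ss_mid.state) == lab_lo:
            lo, state_lo = mid, ss_mid.state
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class WobbleResult:
    """Basin-boundary location along one perturbed species.

    ``wobble_level`` is the midpoint of the final bisection bracket
    ``bracket`` (the boundary depends mildly on protocol, so the bracket is
    reported too); ``feasible`` is False when the boundary lies above the
    confluency ceiling, the irrevertibility situation.
    """

    parameter_value: float
    start_branch: str
    perturbed_species: str
    wobble_level: float | None
    bracket: tuple[float, float] | None
    unstable_level: float | None
    feasible: bool
    target_branch: str | None = None
    note: str = ""


def find_wobble_point(model: NetworkModel, branch_point: BranchPoint,
                      perturbed_species: str, tol_rel: float = 5e-3,
                      far_bound: float | None = None,
                      relax_horizon: float = CONFIRM_HORIZON,
                      classifier: Callable | None = None,
                      unstable_grid: Sequence[float] | None = None
                      ) -> WobbleResult:
    """Bisect the basin boundary along ``perturbed_species``.

    Each probe resets the species to the trial value, relaxes over
    ``relax_horizon`` and classifies the endpoint. ``far_bound`` defaults to
    0 when probing downward from an acute state and to 20x the confluency
    ceiling when probing upward from a chronic state. When both bracket ends
    relax to the starting branch a no-boundary result is returned.
    """
    classify = classifier or (lambda st: classify_branch(model, st))
    ss = branch_point.steady
    names = ss.species_names
    base_level = ss[perturbed_species]
    start_branch = branch_point.branch_label
    f_max = model.parameters.get("F_max", 1000.0)
    if far_bound is None:
        far_bound = 0.0 if start_branch == "acute" else 20.0 * f_max

    def probe(level: float) -> str:
        _, endpoint = perturb_and_relax(model, ss.state, perturbed_species,
                                        level, relax_horizon)
        return classify(endpoint)

    lab_far = probe(far_bound)
    if lab_far == start_branch:
        return WobbleResult(branch_point.parameter_value, start_branch,
                            perturbed_species, None, None, None,
                            feasible=False,
                            note="no boundary: far bound relaxes to start branch")
    near, far = base_level, far_bound
    # bisect until the bracket is narrow relative to its magnitude
    while abs(far - near) > tol_rel * max(abs(near), abs(far), 1e-6):
        mid = 0.5 * (near + far)
        if probe(mid) == start_branch:
            near = mid
        else:
            far = mid
    lo, hi = (near, far) if near <= far else (far, near)
    wobble = 0.5 * (lo + hi)

    unstable_level = None
    if unstable_grid is not None:
        search = find_unstable_state(model, perturbed_species, unstable_grid,
                                     ss.state, known_states=[ss.state])
        if search.found:
            unstable_level = search.result[perturbed_species]
    return WobbleResult(branch_point.parameter_value, start_branch,
                        perturbed_species, wobble, (lo, hi), unstable_level,
                        feasible=wobble <= f_max, target_branch=lab_far)


def eigenvalue_trace(scan: BranchScan) -> pd.DataFrame:
    """Table of (parameter value, max Re eigenvalue) along a scan."""
    rows = [(p.parameter_value,
             p.steady.max_re if p.steady is not None else np.nan,
             p.branch_label)
            for p in scan.points]
    return pd.DataFrame(rows, columns=[scan.parameter_name, "max_re_per_min",
                                       "branch"])


@dataclass
class HeatMap:
    parameter_a: str
    values_a: np.ndarray
    parameter_b: str
    values_b: np.ndarray
    tnf_pM: np.ndarray      # shape (len(values_b), len(values_a))
    failed: np.ndarray      # boolean mask, same shape
    start_mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.values_b):
            for j, a in enumerate(self.values_a):
                rows.append((a, b, self.tnf_pM[i, j], bool(self.failed[i, j])))
        return pd.DataFrame(rows, columns=[self.parameter_a, self.parameter_b,
                                           "TNF_pM", "failed"])

    def to_matrix_file(self, path) -> None:
        """Plain matrix with axis header rows (first row: A values; first
        column: B values)."""
        with open(path, "w") as fh:
            fh.write("# rows: " + self.parameter_b +
                     "; columns: " + self.parameter_a + "; values: TNF_pM\n")
            fh.write("\t".join(["B\\A"] + [f"{a:g}" for a in self.values_a]) + "\n")
            for i, b in enumerate(self.values_b):
                fh.write("\t".join([f"{b:g}"] +
                                   [f"{v:.6g}" for v in self.tnf_pM[i]]) + "\n")


def heat_map(model: NetworkModel, parameter_a: str, values_a: Sequence[float],
             parameter_b: str, values_b: Sequence[float],
             start_mode: str = "acute",
             confirm: bool = False) -> HeatMap:
    """Steady-state TNF (pM) over a two-parameter grid.

    ``start_mode`` fixes the initial-state family per column: ``acute`` seeds
    from the naive near-confluent state, ``chronic`` from the
    fibroblast-free inflamed state. Within each column (fixed ``parameter_a``
    value) the scan over ``parameter_b`` carries state. Failed cells are
    masked, never interpolated.
    """
    values_a = np.asarray(list(values_a), dtype=float)
    values_b = np.asarray(list(values_b), dtype=float)
    tnf = np.full((values_b.size, values_a.size), np.nan)
    failed = np.zeros_like(tnf, dtype=bool)
    for j, a in enumerate(values_a):
        col_model = model.with_parameters(**{parameter_a: a})
        seed = col_model.initial_state()
        if start_mode == "chronic":
            names = col_model.dynamic_species
            seed = seed.copy()
            seed[names.index("fibroblasts")] = 0.0
        carry = None
        for i, b in enumerate(values_b):
            m = col_model.with_parameters(**{parameter_b: b})
            try:
                ss = find_steady_state(m, carry if carry is not None else seed,
                                       classify=confirm,
                                       confirm_horizon=SCAN_CONFIRM_HORIZON)
                carry = ss.state
                tnf[i, j] = ss["TNF"] / 1e3
            except (NoSteadyStateError, RuntimeError):
                failed[i, j] = True
    return HeatMap(parameter_a, values_a, parameter_b, values_b, tnf, failed,
                   start_mode)
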