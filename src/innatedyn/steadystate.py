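"""Steady-state solving, Jacobian/eigenvalue analysis, two-step stability calls.

A state is reported *stable* only when both tests agree: every eigenvalue of
the finite-difference Jacobian has negative real part, and a long
confirmation integration started at the candidate does not drift away from
it. Positive eigenvalues that are attributable to a species sitting below its
reporting floor (the near-extinct-fibroblast situation on the chronic branch)
are annotated, and a frozen-species re-check is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import DEFAULT_ATOL, DEFAULT_RTOL, IntegrationError, integrate
from .network_model import NetworkModel, freeze_species

__all__ = [
    "reduced_spectrum", "SteadyStateResult", "NoSteadyStateError", "UnstableSearch",
    "find_steady_state", "jacobian_eigenvalues", "classify_stability",
    "find_unstable_state", "frozen_species_recheck",
    "STEADY_TOL", "EIGENVALUE_EPS", "CONFIRM_HORIZON", "DRIFT_TOL",
]

#: per-species steady tolerance: max |dx_i/dt| < STEADY_TOL * max(x_i, 1 fM)
STEADY_TOL = 1e-9
#: eigenvalue sign threshold (1/min) for stability calls
EIGENVALUE_EPS = 1e-6
#: default confirmation-integration horizon (min) and per-species drift tolerance
CONFIRM_HORIZON = 1e5
DRIFT_TOL = 1e-3


class NoSteadyStateError(RuntimeError):
    """Neither quiescence nor Newton convergence was reached."""


@dataclass
class SteadyStateResult:
    """A steady state with its spectrum and the two-step stability call."""

    state: np.ndarray
    species_names: list[str]
    residual: float
    jacobian: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    max_re: float | None = None
    label: str = "unclassified"  # stable / unstable / marginal / not_found
    time_course_confirmed: bool = False
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, species: str) -> float:
        return float(self.state[self.species_names.index(species)])

    def state_dict(self) -> dict[str, float]:
        return dict(zip(self.species_names, map(float, self.state)))

    def to_json_dict(self) -> dict:
        return {
            "state_fM": self.state_dict(),
            "residual_fM_per_min": self.residual,
            "eigenvalues_per_min": (
                [[float(z.real), float(z.imag)] for z in self.eigenvalues]
                if self.eigenvalues is not None else None),
            "max_re_per_min": self.max_re,
            "label": self.label,
            "time_course_confirmed": self.time_course_confirmed,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def _residual_ok(y: np.ndarray, dydt: np.ndarray, tol: float = STEADY_TOL) -> bool:
    return bool(np.all(np.abs(dydt) <= tol * np.maximum(np.abs(y), 1.0)))


def jacobian_eigenvalues(model: NetworkModel, state: np.ndarray,
                         rel_step: float = 1e-6, step_floor: float = 1.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Central finite-difference Jacobian of the RHS and its eigen-spectrum.

    The per-species step is ``rel_step * max(|x_i|, step_floor)`` so that
    near-zero species still get a usable probe. Frozen species are excluded
    (the model's RHS already omits them).
    """
    f = model.rhs_fast()
    y = np.asarray(state, dtype=float)
    n = y.size
    if not np.all(np.isfinite(f(0.0, y))):
        raise ValueError("non-finite RHS at the requested state")
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), step_floor)
        yp = y.copy(); yp[j] += h
        ym = y.copy(); ym[j] -= h
        J[:, j] = (f(0.0, yp) - f(0.0, ym)) / (2.0 * h)
    eig = np.linalg.eigvals(J)
    return J, eig


def reduced_spectrum(model: NetworkModel, J: np.ndarray) -> np.ndarray:
    """Eigenvalues of the Jacobian restricted to the stoichiometric subspace.

    Conserved moieties (e.g. the receptor cycle) contribute exact structural
    zero eigenvalues to the full Jacobian; trajectories are confined to the
    affine subspace where the conserved totals are fixed, so stability is
    decided by the spectrum on that subspace. Returns the full spectrum when
    there are no conservation laws.
    """
    from scipy.linalg import null_space
    C = model.conservation_matrix()
    if C.shape[0] == 0:
        return np.linalg.eigvals(J)
    Q = null_space(C)  # orthonormal tangent basis
    return np.linalg.eigvals(Q.T @ J @ Q)


def _eig_with_vectors(model: NetworkModel, state: np.ndarray):
    J, _ = jacobian_eigenvalues(model, state)
    w, V = np.linalg.eig(J)
    return J, w, V


def _near_zero_annotation(model: NetworkModel, y: np.ndarray,
                          w: np.ndarray, V: np.ndarray) -> list[str]:
    """Note positive eigenvalues whose eigenvector lives on sub-floor species."""
    notes = []
    names = model.dynamic_species
    for k in np.where(w.real > EIGENVALUE_EPS)[0]:
        v = np.abs(V[:, k])
        i = int(np.argmax(v))
        floor = model.species_spec(names[i]).floor
        if abs(y[i]) < max(floor, 1e-12):
            notes.append(
                f"positive eigenvalue {w[k].real:.3g}/min attributable to "
                f"near-zero species {names[i]}; frozen-species re-check available")
    return notes


def _damped_newton(model: NetworkModel, y0: np.ndarray,
                   max_iter: int = 60, tol: float = STEADY_TOL
                   ) -> tuple[np.ndarray, float, bool]:
    """Damped Newton polish on the RHS; negative components are clamped to 0.

    Conserved moieties make the full Jacobian singular, so steps are taken in
    the stoichiometric subspace (the conserved totals of the seed are kept).
    """
    from scipy.linalg import null_space

    f = model.rhs_fast()
    y = np.maximum(np.asarray(y0, dtype=float), 0.0)
    fy = f(0.0, y)
    C = model.conservation_matrix()
    Q = null_space(C) if C.shape[0] else None  # tangent basis

    def norm(v, x):
        return float(np.max(np.abs(v) / np.maximum(np.abs(x), 1.0)))

    best = norm(fy, y)
    for _ in range(max_iter):
        if _residual_ok(y, fy, tol):
            break
        J, _ = jacobian_eigenvalues(model, y)
        try:
            if Q is None:
                step = np.linalg.solve(J, -fy)
            else:
                z = np.linalg.solve(Q.T @ J @ Q, -(Q.T @ fy))
                step = Q @ z
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        improved = False
        for _ in range(30):
            y_try = np.maximum(y + lam * step, 0.0)
            f_try = f(0.0, y_try)
            if norm(f_try, y_try) < best:
                y, fy, best = y_try, f_try, norm(f_try, y_try)
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    return y, float(np.max(np.abs(fy))), _residual_ok(y, fy, tol)


def find_steady_state(model: NetworkModel,
                      initial_state: np.ndarray | dict | None = None,
                      horizon_stages: Sequence[float] = (1e4, 1e5, 1e6),
                      classify: bool = True,
                      confirm_horizon: float = CONFIRM_HORIZON,
                      rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                      ) -> SteadyStateResult:
    """Hybrid steady-state solver: integrate to quiescence, then Newton polish.

    The classification step (two-step stability call) is run unless
    ``classify=False``. Raises :class:`NoSteadyStateError` when neither
    integration nor Newton reaches the steady tolerance.
    """
    if initial_state is None:
        y = model.initial_state()
    elif isinstance(initial_state, dict):
        y = model.state_dict_to_vector(initial_state)
    else:
        y = np.asarray(initial_state, dtype=float).copy()
    if np.any(y < 0):
        # tolerate integrator-level negative round-off, reject real negatives
        if np.min(y) < -1e-6 * max(1.0, float(np.max(np.abs(y)))):
            raise ValueError("initial state must be non-negative")
        y = np.maximum(y, 0.0)

    f = model.rhs_fast()
    t_done = 0.0
    for t_stage in horizon_stages:
        traj = integrate(model, y, t_stage - t_done if t_done else t_stage,
                         rtol=rtol, atol=atol)
        y = np.maximum(traj.endpoint, 0.0)
        t_done = t_stage
        if _residual_ok(y, f(0.0, y), tol=1e3 * STEADY_TOL):
            break  # quiescent enough to hand over to Newton

    y_ss, resid, ok = _damped_newton(model, y)
    if not ok:
        dydt = f(0.0, y_ss)
        worst = int(np.argmax(np.abs(dydt) / np.maximum(np.abs(y_ss), 1.0)))
        raise NoSteadyStateError(
            f"no steady state: residual {resid:.3g} fM/min after integration to "
            f"{t_done:.3g} min and Newton polish; worst species "
            f"{model.dynamic_species[worst]}")

    J, w, V = _eig_with_vectors(model, y_ss)
    result = SteadyStateResult(
        state=y_ss, species_names=list(model.dynamic_species),
        residual=resid, jacobian=J, eigenvalues=w,
        max_re=float(np.max(reduced_spectrum(model, J).real)))
    result.notes.extend(_near_zero_annotation(model, y_ss, w, V))
    if classify:
        result = classify_stability(model, result, horizon=confirm_horizon,
                                    rtol=rtol, atol=atol)
    return result


def classify_stability(model: NetworkModel, candidate: SteadyStateResult,
                       horizon: float = CONFIRM_HORIZON,
                       drift_tol: float = DRIFT_TOL,
                       eps: float = EIGENVALUE_EPS,
                       rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                       ) -> SteadyStateResult:
    """Two-step stability call: eigenvalue signs plus confirmation integration.

    ``stable`` requires max Re(lambda) < -eps AND per-species relative drift
    below ``drift_tol`` over ``horizon``; ``unstable`` requires
    max Re(lambda) > +eps OR drift beyond tolerance; anything else is
    ``marginal``.
    """
    y0 = candidate.state
    if candidate.jacobian is None:
        J, w, V = _eig_with_vectors(model, y0)
        candidate.jacobian, candidate.eigenvalues = J, w
        candidate.max_re = float(np.max(reduced_spectrum(model, J).real))
        candidate.notes.extend(_near_zero_annotation(model, y0, w, V))
    traj = integrate(model, y0, horizon, rtol=rtol, atol=atol)
    y1 = traj.endpoint
    drift = np.abs(y1 - y0) / np.maximum(np.abs(y0), 1e-6)
    max_drift = float(np.max(drift))
    confirmed = max_drift < drift_tol
    candidate.time_course_confirmed = confirmed
    if candidate.max_re < -eps and confirmed:
        candidate.label = "stable"
    elif candidate.max_re > eps or not confirmed:
        candidate.label = "unstable"
    else:
        candidate.label = "marginal"
    if not confirmed:
        worst = int(np.argmax(drift))
        candidate.notes.append(
            f"confirmation drift {max_drift:.3g} on "
            f"{candidate.species_names[worst]} over {horizon:.3g} min")
    return candidate


def frozen_species_recheck(model: NetworkModel, result: SteadyStateResult,
                           species: str, value: float = 0.0,
                           **kwargs) -> SteadyStateResult:
    """Re-run the stability analysis with one species clamped.

    Used when a positive eigenvalue is attributable to a species below its
    floor: clamping it (typically to 0) removes the spurious direction from
    the Jacobian and classifies the remaining system.
    """
    frozen = freeze_species(model, species, value)
    names = frozen.dynamic_species
    y0 = np.array([result[n] for n in names])
    return find_steady_state(frozen, y0, **kwargs)


@dataclass
class UnstableSearch:
    """Outcome of a multi-start unstable-state search (never an exception)."""

    found: bool
    result: SteadyStateResult | None
    attempts: list[dict]


def find_unstable_state(model: NetworkModel, scan_species: str,
                        grid: Sequence[float],
                        reference_state: np.ndarray,
                        known_states: Sequence[np.ndarray] = (),
                        distinct_rtol: float = 1e-3,
                        eps: float = EIGENVALUE_EPS,
                        relax_frozen: bool = True) -> UnstableSearch:
    """Multi-start Newton search for an interior unstable steady state.

    Each grid value seeds ``scan_species`` (all other species taken from
    ``reference_state``); the first Newton-converged solution with at least
    one positive-real-part eigenvalue that is distinct from every state in
    ``known_states`` is returned. The grid order is fixed and all attempts
    are logged, so the search is deterministic.
    """
    names = model.dynamic_species
    j = names.index(scan_species)
    attempts: list[dict] = []
    hit: SteadyStateResult | None = None
    for g in grid:
        y0 = np.asarray(reference_state, dtype=float).copy()
        y0[j] = g
        if relax_frozen:
            # quasi-steady seeding: clamp the scanned species at the grid
            # value, relax the remaining (stable) subsystem, then release
            try:
                sub = freeze_species(model, scan_species, g)
                sub_res = find_steady_state(sub, np.delete(y0, j),
                                            classify=False)
                y0 = np.insert(sub_res.state, j, g)
            except (NoSteadyStateError, ValueError):
                pass
        y_ss, resid, ok = _damped_newton(model, y0)
        rec = {"seed": float(g), "converged": ok, "residual": resid}
        if ok:
            rec["solution"] = {scan_species: float(y_ss[j])}
            distinct = all(
                np.max(np.abs(y_ss - np.asarray(ks)) /
                       np.maximum(np.abs(ks), 1.0)) > distinct_rtol
                for ks in known_states)
            if distinct:
                J, w, V = _eig_with_vectors(model, y_ss)
                max_re = float(np.max(reduced_spectrum(model, J).real))
                rec["max_re"] = max_re
                if max_re > eps and hit is None:
                    hit = SteadyStateResult(
                        state=y_ss, species_names=list(names), residual=resid,
                        jacobian=J, eigenvalues=w, max_re=max_re,
                        label="unstable")
                    hit.notes.extend(_near_zero_annotation(model, y_ss, w, V))
        attempts.append(rec)
    return UnstableSearch(found=hit is not None, result=hit, attempts=attempts)
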