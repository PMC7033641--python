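"""Metabolic control analysis by finite perturbation of process activities.

Scaled control coefficients C = d ln(target) / d ln(activity) are computed
for steady-state concentrations and fluxes with respect to each reaction's
dimensionless activity multiplier, by central log-differences with
carry-state re-solving of the steady state. The summation theorems
(concentration coefficients sum to 0, flux coefficients to 1) hold for any
kinetic model and serve as the internal consistency check; coefficients whose
process involves a species below its reporting floor are flagged
non-computable (the "AO" situation) and excluded from the sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network_model import NetworkModel
from .steadystate import SteadyStateResult, _damped_newton

__all__ = [
    "ControlCoefficient", "SummationReport", "BranchJumpError",
    "control_coefficient", "control_profile", "control_vs_parameter_scan",
    "SUMMATION_TOL",
]

#: tolerance for the summation-theorem checks
SUMMATION_TOL = 1e-3
#: default relative perturbation of the activity multiplier
DEFAULT_REL_STEP = 1e-2
#: fallback step used by profiles/scans when the default step jumps branch
FALLBACK_REL_STEP = 1e-3


class BranchJumpError(RuntimeError):
    """The perturbed steady state left the branch; retry with a smaller step."""


@dataclass
class ControlCoefficient:
    target: str                 # species name or "flux:<process_tag>"
    parameter: str              # perturbed process tag
    value: float
    mode: str = ""              # e.g. acute / chronic
    computable: bool = True
    rel_step: float = DEFAULT_REL_STEP
    richardson_value: float | None = None
    note: str = ""


@dataclass
class SummationReport:
    target: str
    kind: str                   # "concentration" or "flux"
    sum_concentration_coeffs: float | None
    sum_flux_coeffs: float | None
    tolerance: float
    passed: bool
    n_computable: int = 0
    n_total: int = 0


def _target_value(model: NetworkModel, y: np.ndarray, target: str) -> float:
    if target.startswith("flux:"):
        tag = target.split(":", 1)[1]
        rates = model.reaction_rates_fast(y)
        tags = [r.process_tag for r in model.reactions]
        return float(rates[tags.index(tag)])
    return float(y[model.dynamic_species.index(target)])


def _involved_species(model: NetworkModel, tag: str) -> set[str]:
    rxn = model.reaction(tag)
    out = {s for s, c in rxn.stoichiometry.items() if c < 0}
    out.update(rxn.rate_law.modifier_species)
    out.update(rxn.rate_law.species.values())
    return out


def _is_computable(model: NetworkModel, y: np.ndarray, tag: str) -> tuple[bool, str]:
    """Non-computable when the process involves a species below its floor."""
    names = model.dynamic_species
    for sp in _involved_species(model, tag):
        spec = model.species_spec(sp)
        if spec.constant or sp in model.frozen:
            continue
        if abs(y[names.index(sp)]) < spec.floor:
            return False, f"species {sp} below floor (AO)"
    return True, ""


def _resolve(model: NetworkModel, seed: np.ndarray) -> np.ndarray:
    """Carry-state steady-state re-solve by Newton from the seed.

    Newton failing to converge from a carried state under a ~1% activity
    perturbation means the branch's solution ceased to exist (fold crossed),
    so the failure is reported as a branch jump rather than papered over by a
    global re-solve, which would silently land on the other attractor.
    """
    y, resid, ok = _damped_newton(model, seed)
    if not ok:
        raise BranchJumpError(
            f"carry-state re-solve did not converge (residual {resid:.3g}); "
            "the perturbation crossed a fold -- use a smaller rel_step")
    return y


def _default_jump_guard(y_base: np.ndarray, y_pert: np.ndarray) -> bool:
    """Heuristic branch-jump detector: any species changing by >10x under a
    ~1% activity perturbation means the solve landed on another attractor."""
    a = np.maximum(np.abs(y_base), 1e-12)
    b = np.maximum(np.abs(y_pert), 1e-12)
    ratio = np.maximum(a / b, b / a)
    big = np.maximum(np.abs(y_base), np.abs(y_pert)) > 1e-6
    return bool(np.any(ratio[big] > 10.0))


def control_coefficient(model: NetworkModel, steady_state: SteadyStateResult,
                        target: str, process_tag: str,
                        rel_step: float = DEFAULT_REL_STEP,
                        mode: str = "",
                        richardson: bool = False,
                        branch_guard: Callable[[np.ndarray, np.ndarray], bool]
                        = _default_jump_guard) -> ControlCoefficient:
    """Scaled control coefficient of ``target`` w.r.t. one process activity.

    Central log-difference: the steady state is re-solved (carry-state,
    seeded from ``steady_state``) at activity (1+s) and (1-s); the value is
    Delta ln(target) / Delta ln(activity). Raises :class:`BranchJumpError`
    when either perturbed solve leaves the branch (``branch_guard``), which is
    the expected near-singular behaviour close to the bifurcation threshold.
    """
    y0 = steady_state.state
    ok, why = _is_computable(model, y0, process_tag)
    if not ok:
        return ControlCoefficient(target, process_tag, 0.0, mode=mode,
                                  computable=False, rel_step=rel_step, note=why)

    def one_sided(s: float) -> float:
        vals = []
        for fac in (1.0 + s, 1.0 - s):
            m = model.with_activity(process_tag, fac)
            y = _resolve(m, y0)
            if branch_guard is not None and branch_guard(y0, y):
                raise BranchJumpError(
                    f"steady state jumped branch while perturbing "
                    f"{process_tag} by {s:+.3g}; use a smaller rel_step")
            vals.append(_target_value(m, y, target))
        v_plus, v_minus = vals
        if v_plus <= 0 or v_minus <= 0:
            # target at (numerical) zero: log-derivative undefined; the
            # coefficient of an absent variable is reported as 0.
            return 0.0
        return (math.log(v_plus) - math.log(v_minus)) / \
               (math.log(1.0 + s) - math.log(1.0 - s))

    value = one_sided(rel_step)
    rich = one_sided(rel_step / 2.0) if richardson else None
    return ControlCoefficient(target, process_tag, value, mode=mode,
                              rel_step=rel_step, richardson_value=rich)


def _coefficient_adaptive(model, steady_state, target, tag, rel_step, mode,
                          step_min: float = 5e-4) -> ControlCoefficient:
    """Coefficient with branch-jump fallback and a Richardson accuracy check.

    The value at step s must agree with the value at s/2 to 1e-3 (absolute)
    + 1e-3 (relative); otherwise the step is halved until agreement or
    ``step_min``. Large-curvature situations (close to a fold) therefore get
    progressively finer probes instead of biased values.
    """
    s = rel_step
    last_exc: BranchJumpError | None = None
    while True:
        try:
            c = control_coefficient(model, steady_state, target, tag,
                                    rel_step=s, mode=mode, richardson=True)
        except BranchJumpError as exc:
            last_exc = exc
            if s / 2 < step_min:
                raise
            s /= 2
            continue
        if not c.computable or c.richardson_value is None:
            return c
        if abs(c.value - c.richardson_value) <= 1e-3 + 1e-3 * abs(c.value):
            if s != rel_step:
                c.note = (c.note + "; " if c.note else "") + \
                    f"step refined to {s:g} from {rel_step:g}"
            # the Richardson value (half step) is the more accurate one
            c.value, c.rel_step = c.richardson_value, s / 2
            return c
        if s / 2 < step_min:
            c.note = (c.note + "; " if c.note else "") + \
                f"Richardson check did not settle at step {s:g}"
            c.value, c.rel_step = c.richardson_value, s / 2
            return c
        s /= 2


def control_profile(model: NetworkModel, steady_state: SteadyStateResult,
                    target: str, mode: str = "",
                    rel_step: float = DEFAULT_REL_STEP,
                    tolerance: float = SUMMATION_TOL
                    ) -> tuple[list[ControlCoefficient], SummationReport]:
    """One coefficient per reaction plus the summation-theorem report.

    Each coefficient carries a Richardson check at half the step; on a branch
    jump or a failed check the step is refined (recorded in the coefficient's
    note), so profiles stay accurate close to the bifurcation threshold.
    """
    coeffs: list[ControlCoefficient] = []
    for rxn in model.reactions:
        coeffs.append(_coefficient_adaptive(model, steady_state, target,
                                            rxn.process_tag, rel_step, mode))
    total = sum(c.value for c in coeffs if c.computable)
    kind = "flux" if target.startswith("flux:") else "concentration"
    expected = 1.0 if kind == "flux" else 0.0
    report = SummationReport(
        target=target, kind=kind,
        sum_concentration_coeffs=total if kind == "concentration" else None,
        sum_flux_coeffs=total if kind == "flux" else None,
        tolerance=tolerance, passed=abs(total - expected) < tolerance,
        n_computable=sum(c.computable for c in coeffs), n_total=len(coeffs))
    return coeffs, report


def profile_to_frame(coeffs: Sequence[ControlCoefficient]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.mode, c.target, c.parameter, c.value, c.computable, c.note)
         for c in coeffs],
        columns=["mode", "target", "process_tag", "value", "computable", "note"])


def control_vs_parameter_scan(model: NetworkModel, branch, target: str,
                              process_tag: str,
                              rel_step: float = DEFAULT_REL_STEP) -> pd.DataFrame:
    """Coefficient along a branch scan, in branch order (carry-state).

    Near-threshold branch jumps are recorded as divergence markers
    (``diverged=True``, value NaN) rather than numbers.
    """
    rows = []
    for pt in branch.points:
        if pt.steady is None:
            rows.append((pt.parameter_value, np.nan, True, "no steady state"))
            continue
        m = model.with_parameters(**{branch.parameter_name: pt.parameter_value})
        try:
            c = control_coefficient(m, pt.steady, target, process_tag,
                                    rel_step=rel_step, mode=pt.branch_label)
            rows.append((pt.parameter_value, c.value, False, c.note))
        except BranchJumpError:
            try:
                c = control_coefficient(m, pt.steady, target, process_tag,
                                        rel_step=FALLBACK_REL_STEP,
                                        mode=pt.branch_label)
                rows.append((pt.parameter_value, c.value, False,
                             "fallback step after branch jump"))
            except BranchJumpError:
                rows.append((pt.parameter_value, np.nan, True,
                             "diverged near threshold"))
    return pd.DataFrame(rows, columns=[branch.parameter_name, "coefficient",
                                       "diverged", "note"])
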