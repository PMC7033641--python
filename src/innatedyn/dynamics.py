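"""Stiff time-course integration with timed intervention events.

Events are instantaneous resets (boluses, parameter switches) applied at
fixed times; the integrator is restarted at every event time. Two events at
the same time are applied in input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network_model import ConfigurationError, NetworkModel
from .units import to_fm

__all__ = ["InterventionEvent", "Trajectory", "IntegrationError",
           "integrate", "perturb_and_relax",
           "DEFAULT_RTOL", "DEFAULT_ATOL"]

#: default integrator tolerances: the reported behaviour must be invariant to
#: tightening these (see the tolerance-halving property in the test suite).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12  # fM


class IntegrationError(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class InterventionEvent:
    """An instantaneous intervention at a fixed time.

    kind
        ``set_species`` (reset a concentration), ``add_species`` (bolus) or
        ``set_parameter`` (switch a kinetic constant).
    magnitude
        value in ``unit`` (concentration units converted exactly to fM;
        parameters are taken as-is).
    """

    time: float
    kind: str
    target: str
    magnitude: float
    unit: str = "fM"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in ("set_species", "add_species", "set_parameter"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class Trajectory:
    """An integrated time course.

    ``states`` has one row per time point, columns aligned with
    ``species_names`` (the model's dynamic species order).
    """

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    events_applied: list[InterventionEvent] = field(default_factory=list)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species_names.index(species)]

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_min, species, value_fM."""
        recs = []
        for j, name in enumerate(self.species_names):
            for t, v in zip(self.times, self.states[:, j]):
                recs.append((t, name, v))
        return pd.DataFrame(recs, columns=["time_min", "species", "value_fM"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "times_min": self.times.tolist(),
            "species": self.species_names,
            "states_fM": self.states.tolist(),
            "events": [vars(e) for e in self.events_applied],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _apply_event(model: NetworkModel, y: np.ndarray,
                 event: InterventionEvent) -> tuple[NetworkModel, np.ndarray]:
    if event.kind == "set_parameter":
        return model.with_parameters(**{event.target: event.magnitude}), y
    names = model.dynamic_species
    if event.target not in names:
        raise ConfigurationError(f"unknown dynamic species {event.target!r}")
    y = y.copy()
    j = names.index(event.target)
    value_fm = to_fm(event.magnitude, event.unit)
    if event.kind == "set_species":
        y[j] = value_fm
    else:
        y[j] += value_fm
    if y[j] < 0:
        raise ValueError(f"event would make {event.target} negative")
    return model, y


def _solve_segment(model: NetworkModel, y0: np.ndarray, t0: float, t1: float,
                   t_eval: np.ndarray | None, rtol: float, atol: float):
    sol = solve_ivp(model.rhs_fast(), (t0, t1), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"integration failed at t={last:.6g} min: {sol.message}", last_time=last)
    return sol


def integrate(model: NetworkModel, initial_state: np.ndarray | Mapping[str, float],
              t_end: float,
              events: Sequence[InterventionEvent] = (),
              output_grid: np.ndarray | None = None,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the model from ``initial_state`` to ``t_end``.

    ``events`` must be sorted by time; each is applied as an instantaneous
    state/parameter reset with the integration restarted there. If
    ``output_grid`` is given, the trajectory is reported on exactly those
    times (plus event times); otherwise the solver's natural steps are kept.
    Concentrations that drift below ``-100*atol`` raise
    :class:`IntegrationError` advising tighter tolerances.
    """
    if isinstance(initial_state, Mapping):
        y = model.state_dict_to_vector(initial_state)
    else:
        y = np.asarray(initial_state, dtype=float).copy()
    if np.any(y < 0):
        raise ValueError("initial state must be non-negative")
    ev = list(events)
    if any(ev[i].time > ev[i + 1].time for i in range(len(ev) - 1)):
        raise ValueError("events must be sorted by time")

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    applied: list[InterventionEvent] = []
    t = 0.0
    m = model
    # events at t<=0 apply before the first segment, in input order
    while ev and ev[0].time <= t:
        e = ev.pop(0)
        m, y = _apply_event(m, y, e)
        applied.append(e)

    segment_ends = sorted({e.time for e in ev if 0.0 < e.time < t_end}) + [t_end]
    for t1 in segment_ends:
        if output_grid is not None:
            grid = np.asarray(output_grid, dtype=float)
            mask = (grid > t) & (grid <= t1)
            t_eval = np.unique(np.concatenate(([t], grid[mask], [t1])))
        else:
            t_eval = None
        sol = _solve_segment(m, y, t, t1, t_eval, rtol, atol)
        times.append(sol.t)
        states.append(sol.y.T)
        y = sol.y[:, -1].copy()
        t = t1
        if np.min(y) < -max(100 * atol, 1e-9 * np.max(np.abs(y))):
            raise IntegrationError(
                f"state went negative beyond tolerance at t={t:.6g} min "
                f"(min {np.min(y):.3g}); tighten rtol/atol", last_time=t)
        np.maximum(y, 0.0, out=y)
        while ev and ev[0].time <= t + 1e-12 and t < t_end:
            e = ev.pop(0)
            m, y = _apply_event(m, y, e)
            applied.append(e)

    all_t = np.concatenate(times)
    all_y = np.vstack(states)
    # enforce strictly increasing times (drop duplicated segment joints)
    keep = np.concatenate(([True], np.diff(all_t) > 0))
    return Trajectory(times=all_t[keep], states=all_y[keep],
                      species_names=model.dynamic_species,
                      events_applied=applied)


def perturb_and_relax(model: NetworkModel, steady_state: np.ndarray,
                      species: str, new_value: float, t_end: float,
                      unit: str = "fM",
                      rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
                      ) -> tuple[Trajectory, np.ndarray]:
    """Reset one species of a steady state and integrate the relaxation.

    Returns the trajectory and its endpoint state; the caller classifies the
    endpoint by branch.
    """
    names = model.dynamic_species
    if species not in names:
        raise ConfigurationError(f"unknown dynamic species {species!r}")
    y0 = np.asarray(steady_state, dtype=float).copy()
    y0[names.index(species)] = to_fm(new_value, unit)
    traj = integrate(model, y0, t_end, rtol=rtol, atol=atol)
    return traj, traj.endpoint
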