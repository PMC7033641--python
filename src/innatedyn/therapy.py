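"""Scenario engine for in-silico experiments on the inflammation model.

Covers the recurrent-infection protease sweep, anti-FLC peptide therapy with
or without fibroblast support, combined TNF/fibroblast interventions, and
fibroblast-influx maps. Outcomes are classified against the acute/chronic
branch structure of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bifurcation import HeatMap, classify_branch, heat_map
from .dynamics import InterventionEvent, Trajectory, integrate
from .network_model import NetworkModel, build_default_model
from .steadystate import NoSteadyStateError, SteadyStateResult, find_steady_state

__all__ = [
    "Scenario", "TherapyOutcome", "InfectionSweepSummary",
    "chronic_steady_state", "acute_steady_state",
    "infection_protease_sweep", "run_therapy",
    "combined_intervention_grid", "fibroblast_influx_therapy",
]

#: outcome thresholds (config switches of the scenario engine). The cure
#: call is branch-based: fibroblasts must repopulate to at least half the
#: confluency ceiling, which on this model separates the families cleanly at
#: every antigen load (TNF levels of the two branches cross at low load and
#: are therefore not usable as a lone cure criterion).
CURE_FIBROBLAST_FRACTION = 0.5   # of F_max
RESPONSE_FRACTION = 0.5          # TNF must drop below this fraction of the
                                 # chronic level to count as a response
#: a checkpoint counts as settled/stable when the TNF level is within this
#: relative distance of the steady state found from it
CHECKPOINT_TNF_RTOL = 0.5

#: bacterial-burst definition: a local maximum is a burst when it exceeds
#: 10x the preceding minimum and an absolute level of 1e-4 fM
PEAK_RATIO = 10.0
PEAK_ABS_FM = 1e-4


def acute_steady_state(model: NetworkModel, **kwargs) -> SteadyStateResult:
    """Steady state from the naive near-confluent initial state."""
    return find_steady_state(model, model.initial_state(), **kwargs)


def chronic_steady_state(model: NetworkModel, **kwargs) -> SteadyStateResult:
    """Steady state of the fibroblast-free (chronic) family.

    Fibroblast extinction is absorbing, so seeding with zero fibroblasts and
    relaxing lands on the chronic attractor directly.
    """
    y0 = model.initial_state()
    y0[model.dynamic_species.index("fibroblasts")] = 0.0
    return find_steady_state(model, y0, **kwargs)


@dataclass
class Scenario:
    """A therapy protocol applied to a chronic steady state.

    ``overrides`` are model configuration overrides (v_CRA, influxes);
    ``interventions`` happen at their stated times (minutes); state and
    stability are recorded at ``checkpoints`` (default 6 h and 24 h).
    """

    overrides: Mapping[str, float] = field(default_factory=dict)
    initial_branch: str = "chronic"
    interventions: list[InterventionEvent] = field(default_factory=list)
    checkpoints: tuple[float, ...] = (360.0, 1440.0)
    horizon: float = 3e4

    def __post_init__(self) -> None:
        if any(c < 0 or c > self.horizon for c in self.checkpoints):
            raise ValueError("checkpoints must lie within [0, horizon]")


@dataclass
class TherapyOutcome:
    scenario: Scenario
    state_at_checkpoints: dict[float, dict[str, float]]
    stability_at_checkpoints: dict[float, str]
    final_state: SteadyStateResult
    final_branch: str
    classification: str  # cured / relapsed / unaffected
    trajectory: Trajectory | None = None

    def tnf_pM_at(self, t: float) -> float:
        return self.state_at_checkpoints[t]["TNF"] / 1e3


def run_therapy(scenario: Scenario, model: NetworkModel | None = None,
                keep_trajectory: bool = False) -> TherapyOutcome:
    """Apply a scenario to the chronic steady state and classify the outcome.

    cured: the final steady state is on the acute branch (fibroblasts at
    least half of F_max and TNF below 1 pM). relapsed: some checkpoint showed
    a TNF response (below half the chronic level) but the final state is
    chronic again. unaffected: TNF never responded.
    """
    if model is None:
        model = build_default_model(scenario.overrides)
    elif scenario.overrides:
        model = model.with_parameters(**scenario.overrides)
    if scenario.initial_branch == "chronic":
        base = chronic_steady_state(model, classify=False)
    else:
        base = acute_steady_state(model, classify=False)
    tnf0 = base["TNF"]

    grid = np.unique(np.concatenate([
        np.linspace(0.0, scenario.horizon, 400), np.array(scenario.checkpoints)]))
    traj = integrate(model, base.state, scenario.horizon,
                     events=sorted(scenario.interventions, key=lambda e: e.time),
                     output_grid=grid)
    # model as of the end of the protocol (parameter switches persist)
    final_model = model
    for e in scenario.interventions:
        if e.kind == "set_parameter":
            final_model = final_model.with_parameters(**{e.target: e.magnitude})

    states_at: dict[float, dict[str, float]] = {}
    stability_at: dict[float, str] = {}
    names = traj.species_names
    for c in scenario.checkpoints:
        i = int(np.argmin(np.abs(traj.times - c)))
        y_c = np.maximum(traj.states[i], 0.0)
        states_at[c] = dict(zip(names, map(float, y_c)))
        # a checkpoint is "stable" when the steady state reached from it is
        # stable AND the checkpoint has essentially arrived there (TNF within
        # CHECKPOINT_TNF_RTOL); a transient still far from its attractor is
        # reported unstable.
        try:
            ss_c = find_steady_state(final_model, y_c, classify=True,
                                     confirm_horizon=2e4)
            tnf_c = y_c[names.index("TNF")]
            settled = abs(tnf_c - ss_c["TNF"]) <= CHECKPOINT_TNF_RTOL * max(
                ss_c["TNF"], 1.0)
            stability_at[c] = "stable" if (ss_c.label == "stable" and settled) \
                else "unstable"
        except NoSteadyStateError:
            stability_at[c] = "unstable"

    final = find_steady_state(final_model, traj.endpoint, classify=False)
    final_branch = classify_branch(final_model, final.state)
    cured = final_branch == "acute"

    responded = any(s["TNF"] < RESPONSE_FRACTION * tnf0 for s in states_at.values())
    responded = responded or bool(np.any(traj["TNF"] < RESPONSE_FRACTION * tnf0))
    if cured:
        classification = "cured"
    elif responded:
        classification = "relapsed"
    else:
        classification = "unaffected"
    return TherapyOutcome(scenario, states_at, stability_at, final,
                          final_branch, classification,
                          trajectory=traj if keep_trajectory else None)


# --------------------------------------------------------------------------- #
# combined interventions (TNF reset x fibroblast implantation)
# --------------------------------------------------------------------------- #

def combined_intervention_grid(model: NetworkModel, v_CRA: float,
                               tnf_resets_pM: Sequence[float | None],
                               fibroblast_resets_fM: Sequence[float | None],
                               horizon: float = 5e4) -> pd.DataFrame:
    """Simultaneous TNF reset and fibroblast implantation at t=0.

    Each cell resets TNF (pM; None = untreated) and fibroblasts (fM; None =
    untreated) of the chronic steady state, relaxes to steady state and
    reports final fibroblasts (fM), final TNF (pM) and the cure call.
    """
    m = model.with_parameters(v_CRA=v_CRA)
    base = chronic_steady_state(m, classify=False)
    names = base.species_names
    rows = []
    for tnf_reset in tnf_resets_pM:
        for fib_reset in fibroblast_resets_fM:
            y0 = base.state.copy()
            if tnf_reset is not None:
                y0[names.index("TNF")] = tnf_reset * 1e3
            if fib_reset is not None:
                y0[names.index("fibroblasts")] = fib_reset
            traj = integrate(m, y0, horizon)
            final = find_steady_state(m, traj.endpoint, classify=False)
            cured = classify_branch(m, final.state) == "acute"

            rows.append((
                "none" if tnf_reset is None else f"{base['TNF']/1e3:.3g}->{tnf_reset:g}",
                "none" if fib_reset is None else f"{base['fibroblasts']:.3g}->{fib_reset:g}",
                final["fibroblasts"], final["TNF"] / 1e3, cured))
    return pd.DataFrame(rows, columns=["TNF_treatment_pM", "fibroblast_implantation_fM",
                                       "final_fibroblasts_fM", "final_TNF_pM", "cured"])


# --------------------------------------------------------------------------- #
# infection / protease sweep
# --------------------------------------------------------------------------- #

@dataclass
class InfectionSweepSummary:
    protease_influx: float
    peak_count: int
    interpeak_minimum: float | None  # fM, between first and second burst
    final_label: str                 # recurrent / resolved
    final_max_re: float | None = None


def _count_bursts(times: np.ndarray, bact: np.ndarray
                  ) -> tuple[int, float | None]:
    """Count bacterial bursts: local maxima above PEAK_ABS_FM exceeding
    PEAK_RATIO times the preceding minimum. Returns (count, minimum between
    first and second burst)."""
    peaks = []
    mins_before = []
    running_min = bact[0] if bact.size else 0.0
    running_min_since_peak = running_min
    for i in range(1, len(bact) - 1):
        if bact[i] >= bact[i - 1] and bact[i] > bact[i + 1]:
            level = bact[i]
            if level > PEAK_ABS_FM and level > PEAK_RATIO * max(running_min_since_peak,
                                                                1e-300):
                peaks.append(i)
                mins_before.append(running_min_since_peak)
                running_min_since_peak = level
        running_min_since_peak = min(running_min_since_peak, bact[i])
    interpeak = float(mins_before[1]) if len(mins_before) >= 2 else None
    return len(peaks), interpeak


def infection_protease_sweep(model: NetworkModel,
                             protease_influx_values: Sequence[float],
                             horizon: float = 4e4,
                             bacteria_initial: float = 1.0,
                             n_output: int = 4000) -> list[InfectionSweepSummary]:
    """Re-run the infection at several steady protease-influx magnitudes.

    The model must include bacteria; ``bacteria_initial`` (fM) seeds the
    infection on top of the model's initial state. Per influx value the time
    course is integrated, bacterial bursts are counted, and the endpoint is
    checked for a stable steady state with bacteria below floor (resolved)
    or not (recurrent).
    """
    names = model.dynamic_species
    if "bacteria" not in names:
        raise ValueError("model has no bacteria species")
    summaries = []
    grid = np.linspace(0.0, horizon, n_output)
    for v in protease_influx_values:
        m = model.with_parameters(v_protease=v)
        y0 = m.initial_state()
        y0[names.index("bacteria")] = bacteria_initial
        traj = integrate(m, y0, horizon, output_grid=grid)
        bact = traj["bacteria"]
        n_peaks, interpeak = _count_bursts(traj.times, bact)
        final_max_re = None
        label = "recurrent"
        try:
            ss = find_steady_state(m, traj.endpoint, classify=True,
                                   confirm_horizon=2e4)
            final_max_re = ss.max_re
            floor = m.species_spec("bacteria").floor
            if ss.label == "stable" and ss["bacteria"] < max(floor, 1e-12):
                label = "resolved"
        except NoSteadyStateError:
            pass
        summaries.append(InfectionSweepSummary(v, n_peaks, interpeak, label,
                                               final_max_re))
    return summaries


def fibroblast_influx_therapy(model: NetworkModel,
                              v_CRA_values: Sequence[float],
                              influx_values: Sequence[float],
                              start_mode: str = "chronic") -> HeatMap:
    """Steady TNF map over antigen load x fibroblast influx (delegates to
    the two-parameter heat map)."""
    return heat_map(model, "v_CRA", v_CRA_values,
                    "v_fibroblast", influx_values, start_mode=start_mode)
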