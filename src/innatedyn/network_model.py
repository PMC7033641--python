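"""Kinetic network definition for the innate-immunity model and toy fixtures.

The model couples cellular players (fibroblasts, bacteria, constant pools of
B cells and mast cells) with molecular mediators (cross-reactive antigen CRA,
free immunoglobulin light chains FLC, TNF, MMP7, MMP8, an anti-FLC peptide,
and a bacteriolytic protease) in a single well-mixed volume. Concentrations
are femtomolar, time is minutes.

The inflammation circuit
------------------------
Mast-cell receptors are loaded by FLC and crosslinked by CRA; crosslinked
(activated) receptors drive TNF and protease production. TNF kills healthy
fibroblasts (cooperatively) and stimulates fibroblasts to secrete CRA, while
fibroblast-released MMP7 clips additional CRA off the fibroblast surface
(pro-inflammatory) and MMP8 neutralises CRA (anti-inflammatory). Healthy
fibroblasts grow logistically up to the confluency ceiling ``F_max`` (1000 fM,
i.e. 1.7 pl per cell filling all space). Fibroblast extinction is absorbing
(growth is autocatalytic), which makes the high-TNF, fibroblast-free
"chronic" state a distinct family of steady states next to the low-TNF,
near-confluent "acute" family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "SpeciesSpec",
    "RateLaw",
    "ReactionSpec",
    "NetworkModel",
    "ConfigurationError",
    "ModelValidationError",
    "build_default_model",
    "build_inflammation_model",
    "build_toy_model",
    "freeze_species",
    "DEFAULT_PARAMETERS",
]


class ConfigurationError(ValueError):
    """An override names an unknown species or parameter."""


class ModelValidationError(ValueError):
    """A model definition violates a structural invariant."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical or cellular species.

    ``floor`` is the concentration below which the species is *reported* as
    zero and treated as absent for control-coefficient computability; it never
    alters the dynamics.
    """

    name: str
    unit: str = "fM"
    role: str = "molecule"  # or "cell"
    floor: float = 1e-30
    constant: bool = False
    initial: float = 0.0

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ModelValidationError(f"species {self.name}: floor must be >= 0")
        if self.role not in ("molecule", "cell"):
            raise ModelValidationError(f"species {self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class RateLaw:
    """A tagged kinetic rate-law family.

    ``form`` selects the functional family; ``parameters`` maps the family's
    parameter roles to *global parameter names* resolved against
    ``NetworkModel.parameters``; ``species`` maps the family's species roles
    (driver, stimulus, ...) to species names. ``modifier_species`` are species
    that appear in the rate but are not consumed.
    """

    form: str
    parameters: Mapping[str, str] = field(default_factory=dict)
    species: Mapping[str, str] = field(default_factory=dict)
    modifier_species: tuple[str, ...] = ()
    expression: Callable[..., float] | None = None  # only for form="expression"

    FORMS = (
        "zero_order_influx",
        "first_order_washout",
        "mass_action",
        "saturable",
        "logistic_growth",
        "product_of_species",
        "expression",
    )

    def __post_init__(self) -> None:
        if self.form not in self.FORMS:
            raise ModelValidationError(f"unknown rate-law form {self.form!r}")


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction: signed stoichiometry plus a rate law and a process tag.

    ``process_tag`` is the category label used by the control analysis; it is
    unique per reaction so that each process carries its own activity
    multiplier.
    """

    name: str
    stoichiometry: Mapping[str, float]
    rate_law: RateLaw
    process_tag: str


@dataclass
class NetworkModel:
    """A complete kinetic network.

    Frozen species keep appearing in rate laws at their clamped value but
    contribute no time derivative. ``parameters`` is the flat table of all
    kinetic constants; ``activities`` holds one dimensionless multiplier per
    process tag (all 1.0 by default) used by the control analysis.
    """

    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    parameters: dict[str, float]
    constants: dict[str, float] = field(default_factory=dict)
    frozen: dict[str, float] = field(default_factory=dict)
    provenance: str = "default"
    activities: dict[str, float] = field(default_factory=dict)

    # -- construction helpers ------------------------------------------------
    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate species names")
        tags = [r.process_tag for r in self.reactions]
        if len(set(tags)) != len(tags):
            raise ModelValidationError("process tags must be unique per reaction")
        declared = set(names)
        for rxn in self.reactions:
            for sp in rxn.stoichiometry:
                if sp not in declared:
                    raise ModelValidationError(
                        f"reaction {rxn.name}: undeclared species {sp!r}")
        for tag in tags:
            self.activities.setdefault(tag, 1.0)
        self._compiled = None

    # -- basic queries -------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def dynamic_species(self) -> list[str]:
        """Species that carry a time derivative (not constant, not frozen)."""
        return [s.name for s in self.species
                if not s.constant and s.name not in self.frozen]

    def species_spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def reaction(self, tag_or_name: str) -> ReactionSpec:
        for r in self.reactions:
            if r.process_tag == tag_or_name or r.name == tag_or_name:
                return r
        raise KeyError(tag_or_name)

    # -- copies / modification ----------------------------------------------
    def copy(self) -> "NetworkModel":
        return NetworkModel(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=dict(self.parameters),
            constants=dict(self.constants),
            frozen=dict(self.frozen),
            provenance=self.provenance,
            activities=dict(self.activities),
        )

    def with_parameters(self, **overrides: float) -> "NetworkModel":
        """Return a copy with parameter values replaced.

        Raises :class:`ConfigurationError` for unknown parameter names.
        """
        m = self.copy()
        for key, value in overrides.items():
            if key not in m.parameters:
                raise ConfigurationError(f"unknown parameter {key!r}")
            m.parameters[key] = float(value)
        return m

    def with_activity(self, process_tag: str, value: float) -> "NetworkModel":
        if process_tag not in self.activities:
            raise ConfigurationError(f"unknown process tag {process_tag!r}")
        m = self.copy()
        m.activities[process_tag] = float(value)
        return m

    # -- state vector plumbing ----------------------------------------------
    def initial_state(self) -> np.ndarray:
        """Initial concentrations for the *dynamic* species, in species order."""
        return np.array([self.species_spec(n).initial for n in self.dynamic_species])

    def full_state(self, y: np.ndarray) -> dict[str, float]:
        """Assemble the complete name->concentration map from a dynamic vector."""
        state = {}
        it = iter(np.asarray(y, dtype=float))
        dynamic = set(self.dynamic_species)
        for s in self.species:
            if s.name in self.frozen:
                state[s.name] = self.frozen[s.name]
            elif s.constant:
                state[s.name] = s.initial
            else:
                state[s.name] = float(next(it))
        assert len(state) == len(self.species)
        # any leftover would be a programming error
        _ = dynamic
        return state

    # -- rate evaluation -----------------------------------------------------
    def reaction_rate(self, rxn: ReactionSpec, state: Mapping[str, float]) -> float:
        """Evaluate one reaction's rate (fM/min) including its activity."""
        law = rxn.rate_law
        p = self.parameters
        act = self.activities.get(rxn.process_tag, 1.0)
        form = law.form
        if form == "zero_order_influx":
            v = p[law.parameters["rate"]]
            return act * v
        if form == "first_order_washout":
            k = p[law.parameters["k"]]
            (sp,) = [s for s, c in rxn.stoichiometry.items() if c < 0]
            return act * k * state[sp]
        if form == "mass_action":
            k = p[law.parameters["k"]]
            rate = k
            for sp, coeff in rxn.stoichiometry.items():
                if coeff < 0:
                    rate *= state[sp] ** (-coeff)
            for sp in law.modifier_species:
                rate *= state[sp]
            return act * rate
        if form == "product_of_species":
            k = p[law.parameters["k"]]
            rate = k
            for sp in law.modifier_species:
                rate *= state[sp]
            return act * rate
        if form == "saturable":
            k = p[law.parameters["k"]]
            K = p[law.parameters["K"]]
            n = p[law.parameters["n"]] if "n" in law.parameters else 1.0
            s_val = state[law.species["stimulus"]]
            hill = (s_val ** n) / (K ** n + s_val ** n) if (K ** n + s_val ** n) != 0 else 0.0
            driver = state[law.species["driver"]] if "driver" in law.species else 1.0
            return act * k * driver * hill
        if form == "logistic_growth":
            r = p[law.parameters["r"]]
            cap = p[law.parameters["capacity"]]
            x = state[law.species["grower"]]
            return act * r * x * (1.0 - x / cap)
        if form == "expression":
            return act * law.expression(state, p)
        raise AssertionError(form)

    def reaction_rates(self, state: Mapping[str, float]) -> np.ndarray:
        return np.array([self.reaction_rate(r, state) for r in self.reactions])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the dynamic state vector (fM/min)."""
        state = self.full_state(y)
        rates = self.reaction_rates(state)
        deriv = dict.fromkeys(self.dynamic_species, 0.0)
        for rxn, rate in zip(self.reactions, rates):
            for sp, coeff in rxn.stoichiometry.items():
                if sp in deriv:
                    deriv[sp] += coeff * rate
        return np.array([deriv[n] for n in self.dynamic_species])

    def state_dict_to_vector(self, state: Mapping[str, float]) -> np.ndarray:
        return np.array([state[n] for n in self.dynamic_species])

    # -- compiled fast path ---------------------------------------------------
    def _compile(self):
        """Precompute index-based rate closures and the stoichiometry matrix.

        The compiled form is equivalent to :meth:`rhs` but avoids per-call
        dict construction; it is rebuilt lazily whenever a new model object is
        created (copies never share compiled state).
        """
        idx = {s.name: i for i, s in enumerate(self.species)}
        template = np.empty(len(self.species))
        for i, s in enumerate(self.species):
            if s.name in self.frozen:
                template[i] = self.frozen[s.name]
            elif s.constant:
                template[i] = s.initial
            else:
                template[i] = np.nan  # filled per call
        dyn_pos = np.array([idx[n] for n in self.dynamic_species], dtype=int)

        rate_fns = []
        p = self.parameters
        for rxn in self.reactions:
            law = rxn.rate_law
            act = self.activities.get(rxn.process_tag, 1.0)
            form = law.form
            if form == "zero_order_influx":
                v = act * p[law.parameters["rate"]]
                rate_fns.append(lambda full, v=v: v)
            elif form == "first_order_washout":
                k = act * p[law.parameters["k"]]
                (sp,) = [s for s, c in rxn.stoichiometry.items() if c < 0]
                j = idx[sp]
                rate_fns.append(lambda full, k=k, j=j: k * full[j])
            elif form in ("mass_action", "product_of_species"):
                k = act * p[law.parameters["k"]]
                factors: list[tuple[int, float]] = []
                if form == "mass_action":
                    for sp, coeff in rxn.stoichiometry.items():
                        if coeff < 0:
                            factors.append((idx[sp], -coeff))
                for sp in law.modifier_species:
                    factors.append((idx[sp], 1.0))

                def f(full, k=k, factors=tuple(factors)):
                    r = k
                    for j, e in factors:
                        r *= full[j] if e == 1.0 else full[j] ** e
                    return r
                rate_fns.append(f)
            elif form == "saturable":
                k = act * p[law.parameters["k"]]
                K = p[law.parameters["K"]]
                n = p[law.parameters["n"]] if "n" in law.parameters else 1.0
                js = idx[law.species["stimulus"]]
                jd = idx[law.species["driver"]] if "driver" in law.species else None
                Kn = K ** n

                def f(full, k=k, Kn=Kn, n=n, js=js, jd=jd):
                    s = full[js]
                    sn = s ** n
                    r = k * sn / (Kn + sn)
                    if jd is not None:
                        r *= full[jd]
                    return r
                rate_fns.append(f)
            elif form == "logistic_growth":
                r0 = act * p[law.parameters["r"]]
                cap = p[law.parameters["capacity"]]
                j = idx[law.species["grower"]]
                rate_fns.append(
                    lambda full, r0=r0, cap=cap, j=j: r0 * full[j] * (1.0 - full[j] / cap))
            elif form == "expression":
                names = [s.name for s in self.species]
                expr = law.expression

                def f(full, expr=expr, names=names, act=act, p=p):
                    state = dict(zip(names, full))
                    return act * expr(state, p)
                rate_fns.append(f)
            else:  # pragma: no cover
                raise AssertionError(form)

        n_dyn = len(dyn_pos)
        S = np.zeros((n_dyn, len(self.reactions)))
        pos_of = {int(j): i for i, j in enumerate(dyn_pos)}
        for jr, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoichiometry.items():
                i = idx[sp]
                if i in pos_of:
                    S[pos_of[i], jr] += coeff
        self._compiled = (template, dyn_pos, rate_fns, S)
        return self._compiled

    def stoichiometry_matrix(self) -> np.ndarray:
        """Stoichiometry matrix over dynamic species (rows) x reactions."""
        template, dyn_pos, rate_fns, S = self._compiled or self._compile()
        return S

    def conservation_matrix(self) -> np.ndarray:
        """Rows spanning the conserved moieties: c with c @ S == 0.

        Each row is a linear combination of species whose total is invariant
        under the dynamics (e.g. the mast-cell receptor cycle). Empty (0 x n)
        when there are none.
        """
        from scipy.linalg import null_space
        S = self.stoichiometry_matrix()
        C = null_space(S.T, rcond=1e-10).T
        return C if C.size else np.zeros((0, S.shape[0]))

    def rhs_fast(self):
        """Return ``f(t, y)`` suitable for ``scipy.integrate.solve_ivp``."""
        template, dyn_pos, rate_fns, S = self._compiled or self._compile()

        def f(t, y):
            full = template.copy()
            full[dyn_pos] = y
            rates = np.array([fn(full) for fn in rate_fns])
            return S @ rates
        return f

    def reaction_rates_fast(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction rates (activity included) from a dynamic state vector."""
        template, dyn_pos, rate_fns, _ = self._compiled or self._compile()
        full = template.copy()
        full[dyn_pos] = y
        return np.array([fn(full) for fn in rate_fns])

    def apply_floor(self, state: Mapping[str, float]) -> dict[str, float]:
        """Reporting helper: values below a species' floor become exactly 0."""
        out = {}
        for name, value in state.items():
            try:
                floor = self.species_spec(name).floor
            except KeyError:
                floor = 0.0
            out[name] = 0.0 if abs(value) < floor else value
        return out


# --------------------------------------------------------------------------- #
# default innate-immunity model
# --------------------------------------------------------------------------- #

#: All kinetic constants of the default model (units: fM, min). These values
#: were calibrated once so that the model exhibits the documented qualitative
#: repertoire: bistability between a near-confluent low-TNF acute family and a
#: fibroblast-free high-TNF chronic family; an acute-branch collapse threshold
#: in the CRA influx; irrevertibility of the chronic state under antigen
#: withdrawal; peptide-therapy relapse vs. cure with fibroblast support; and
#: recurrent bacterial bursts under sub-lytic protease influx.
DEFAULT_PARAMETERS: dict[str, float] = {
    # cross-reactive antigen (CRA)
    "v_CRA": 1.0,                 # fM/min, zero-order influx (bifurcation parameter)
    "k_CRA_washout": 6e-4,        # /min, lymph clearance of free CRA
    "k_CRA_neutralisation": 2e-3, # /fM/min, MMP8-mediated CRA removal
    "k_CRA_secretion": 1e-4,      # /min per fM fibroblast, TNF-stimulated
    "K_CRA_secretion": 1000.0,    # fM TNF at half-maximal secretion
    "n_CRA_secretion": 1.0,
    "k_CRA_clipoff": 1e-6,        # /fM/min per fM fibroblast (MMP7-assisted)
    # free immunoglobulin light chains (FLC)
    "k_FLC_production": 10.0,     # /min per fM B cells
    "k_FLC_washout": 0.01,        # /min
    # mast-cell receptor states
    "k_receptor_on": 1e-4,        # /fM/min, FLC loading
    "k_receptor_off": 0.01,       # /min, FLC unloading
    "k_crosslink": 6e-4,          # /fM/min, CRA crosslinking of loaded receptors
    "k_crosslink_decay": 0.03,    # /min, internalisation/recycling to free receptor
    # TNF
    "k_TNF_production": 50.0,     # /min per fM crosslinked receptor
    "k_TNF_washout": 0.01,        # /min
    # MMPs released by fibroblasts
    "k_MMP7_release": 0.01,       # /min per fM fibroblast (pro-inflammatory)
    "k_MMP7_washout": 0.05,
    "k_MMP8_release": 0.01,       # /min per fM fibroblast (anti-inflammatory)
    "k_MMP8_washout": 0.05,
    # healthy fibroblasts
    "k_fibroblast_growth": 0.01,  # /min, logistic
    "F_max": 1000.0,              # fM confluency ceiling ("total space")
    "k_fibroblast_kill": 0.3,     # /min, maximal TNF-mediated killing
    "K_kill": 40000.0,            # fM TNF (40 pM) at half-maximal killing
    "n_kill": 4.0,                # cooperativity of TNF-induced killing
    "k_fibroblast_washout": 1e-5, # /min (adherent cells clear far slower than solutes)
    "v_fibroblast": 0.0,          # fM/min, optional therapeutic influx
    "death_release_CRA": 0.0,     # fM CRA released per fM fibroblast killed
    # anti-FLC peptide
    "k_peptide_binding": 1e-3,    # /fM/min, irreversible FLC neutralisation
    "k_peptide_washout": 0.008,   # /min
    # bacteria and protease
    "k_bacteria_growth": 0.1,     # /min, logistic
    "B_capacity": 1e5,            # fM
    "k_bacteria_washout": 1e-3,
    "k_lysis": 0.01,              # /fM/min, protease-mediated lysis
    "k_antigen_shedding": 5e-4,   # /min per fM bacteria -> CRA
    "k_protease_production": 0.3, # /min per fM crosslinked receptor
    "v_protease": 0.0,            # fM/min, optional therapeutic influx
    "k_protease_washout": 0.01,
    # constant cellular pools
    "B_cells": 1.0,               # fM
    "mast_cells": 0.1,            # fM
}

#: total mast-cell receptor pool (fM); split over free/loaded/crosslinked states
DEFAULT_RECEPTOR_TOTAL = 10.0


def _default_species(params: Mapping[str, float]) -> list[SpeciesSpec]:
    return [
        SpeciesSpec("CRA"),
        SpeciesSpec("FLC"),
        SpeciesSpec("TNF"),
        SpeciesSpec("MMP7"),
        SpeciesSpec("MMP8"),
        SpeciesSpec("R_free", initial=DEFAULT_RECEPTOR_TOTAL),
        SpeciesSpec("R_FLC"),
        SpeciesSpec("R_cross"),
        SpeciesSpec("fibroblasts", role="cell", initial=params["F_max"]),
        SpeciesSpec("peptide"),
        SpeciesSpec("bacteria", role="cell"),
        SpeciesSpec("protease"),
        SpeciesSpec("B_cells", role="cell", constant=True, initial=params["B_cells"]),
        SpeciesSpec("mast_cells", role="cell", constant=True, initial=params["mast_cells"]),
    ]


def _default_reactions() -> list[ReactionSpec]:
    R = ReactionSpec
    L = RateLaw
    return [
        # --- antigen -------------------------------------------------------
        R("CRA influx", {"CRA": +1},
          L("zero_order_influx", {"rate": "v_CRA"}), "CRA_influx"),
        R("CRA washout", {"CRA": -1},
          L("first_order_washout", {"k": "k_CRA_washout"}), "washout_CRA"),
        R("CRA neutralisation by MMP8", {"CRA": -1},
          L("mass_action", {"k": "k_CRA_neutralisation"}, modifier_species=("MMP8",)),
          "CRA_degradation"),
        R("TNF-stimulated CRA secretion", {"CRA": +1},
          L("saturable", {"k": "k_CRA_secretion", "K": "K_CRA_secretion",
                          "n": "n_CRA_secretion"},
            species={"driver": "fibroblasts", "stimulus": "TNF"},
            modifier_species=("fibroblasts", "TNF")),
          "CRA_secretion"),
        R("CRA clip-off from fibroblasts", {"CRA": +1},
          L("product_of_species", {"k": "k_CRA_clipoff"},
            modifier_species=("fibroblasts", "MMP7")),
          "CRA_clipoff"),
        # --- FLC -----------------------------------------------------------
        R("FLC production by B cells", {"FLC": +1},
          L("product_of_species", {"k": "k_FLC_production"},
            modifier_species=("B_cells",)),
          "FLC_production"),
        R("FLC washout", {"FLC": -1},
          L("first_order_washout", {"k": "k_FLC_washout"}), "washout_FLC"),
        # --- receptor cycle -------------------------------------------------
        R("FLC-receptor binding", {"FLC": -1, "R_free": -1, "R_FLC": +1},
          L("mass_action", {"k": "k_receptor_on"}), "FLC_receptor_binding"),
        R("FLC-receptor release", {"R_FLC": -1, "R_free": +1, "FLC": +1},
          L("first_order_washout", {"k": "k_receptor_off"}), "FLC_receptor_release"),
        R("receptor crosslinking by CRA", {"CRA": -1, "R_FLC": -1, "R_cross": +1},
          L("mass_action", {"k": "k_crosslink"}), "receptor_crosslinking"),
        R("crosslinked-receptor recycling", {"R_cross": -1, "R_free": +1},
          L("first_order_washout", {"k": "k_crosslink_decay"}), "receptor_recycling"),
        # --- TNF -----------------------------------------------------------
        R("TNF production by activated mast cells", {"TNF": +1},
          L("product_of_species", {"k": "k_TNF_production"},
            modifier_species=("R_cross",)),
          "TNF_production"),
        R("TNF washout", {"TNF": -1},
          L("first_order_washout", {"k": "k_TNF_washout"}), "TNF_washout"),
        # --- MMPs ----------------------------------------------------------
        R("MMP7 release by fibroblasts", {"MMP7": +1},
          L("product_of_species", {"k": "k_MMP7_release"},
            modifier_species=("fibroblasts",)),
          "MMP7_release"),
        R("MMP7 washout", {"MMP7": -1},
          L("first_order_washout", {"k": "k_MMP7_washout"}), "washout_MMP7"),
        R("MMP8 release by fibroblasts", {"MMP8": +1},
          L("product_of_species", {"k": "k_MMP8_release"},
            modifier_species=("fibroblasts",)),
          "MMP8_release"),
        R("MMP8 washout", {"MMP8": -1},
          L("first_order_washout", {"k": "k_MMP8_washout"}), "washout_MMP8"),
        # --- fibroblasts ---------------------------------------------------
        R("fibroblast logistic growth", {"fibroblasts": +1},
          L("logistic_growth", {"r": "k_fibroblast_growth", "capacity": "F_max"},
            species={"grower": "fibroblasts"}),
          "fibroblast_growth"),
        R("TNF-mediated fibroblast killing",
          {"fibroblasts": -1, "CRA": 0.0},  # CRA release on death via config switch
          L("saturable", {"k": "k_fibroblast_kill", "K": "K_kill", "n": "n_kill"},
            species={"driver": "fibroblasts", "stimulus": "TNF"},
            modifier_species=("TNF",)),
          "fibroblast_killing"),
        R("fibroblast washout", {"fibroblasts": -1},
          L("first_order_washout", {"k": "k_fibroblast_washout"}),
          "washout_fibroblasts"),
        R("fibroblast influx", {"fibroblasts": +1},
          L("zero_order_influx", {"rate": "v_fibroblast"}), "fibroblast_influx"),
        # --- peptide -------------------------------------------------------
        R("peptide-FLC binding", {"peptide": -1, "FLC": -1},
          L("mass_action", {"k": "k_peptide_binding"}), "peptide_binding"),
        R("peptide washout", {"peptide": -1},
          L("first_order_washout", {"k": "k_peptide_washout"}), "washout_peptide"),
        # --- bacteria & protease -------------------------------------------
        R("bacterial growth", {"bacteria": +1},
          L("logistic_growth", {"r": "k_bacteria_growth", "capacity": "B_capacity"},
            species={"grower": "bacteria"}),
          "bacteria_growth"),
        R("protease-mediated bacterial lysis", {"bacteria": -1},
          L("mass_action", {"k": "k_lysis"}, modifier_species=("protease",)),
          "bacteria_lysis"),
        R("bacteria washout", {"bacteria": -1},
          L("first_order_washout", {"k": "k_bacteria_washout"}), "washout_bacteria"),
        R("antigen shedding by bacteria", {"CRA": +1},
          L("product_of_species", {"k": "k_antigen_shedding"},
            modifier_species=("bacteria",)),
          "bacteria_antigen_shedding"),
        R("protease production by activated mast cells", {"protease": +1},
          L("product_of_species", {"k": "k_protease_production"},
            modifier_species=("R_cross",)),
          "protease_production"),
        R("protease influx", {"protease": +1},
          L("zero_order_influx", {"rate": "v_protease"}), "protease_influx"),
        R("protease washout", {"protease": -1},
          L("first_order_washout", {"k": "k_protease_washout"}), "washout_protease"),
    ]


def build_default_model(config: Mapping[str, float] | None = None) -> NetworkModel:
    """Build the default innate-immunity model.

    ``config`` may override any entry of :data:`DEFAULT_PARAMETERS` (unknown
    keys raise :class:`ConfigurationError`) and, with keys of the form
    ``initial:<species>``, the initial concentration of a species. The
    ``death_release_CRA`` switch adds a pro-inflammatory CRA release term to
    the fibroblast-killing reaction (dying fibroblasts shedding antigen); it
    defaults to 0.
    """
    params = dict(DEFAULT_PARAMETERS)
    initial_overrides: dict[str, float] = {}
    if config:
        for key, value in config.items():
            if key.startswith("initial:"):
                initial_overrides[key.split(":", 1)[1]] = float(value)
            elif key in params:
                params[key] = float(value)
            else:
                raise ConfigurationError(f"unknown configuration key {key!r}")
    if params["F_max"] <= 0:
        raise ModelValidationError("F_max (confluency ceiling) must be positive")

    species = _default_species(params)
    reactions = _default_reactions()
    # dying-fibroblast pro-inflammatory release: implemented as CRA
    # stoichiometry on the killing reaction, controlled by the config switch.
    rho = params["death_release_CRA"]
    reactions = [
        replace(r, stoichiometry={"fibroblasts": -1, "CRA": rho})
        if r.process_tag == "fibroblast_killing" else r
        for r in reactions
    ]

    model = NetworkModel(
        species=species,
        reactions=reactions,
        parameters=params,
        constants={"F_max": params["F_max"], "default_horizon": 1e5,
                   "receptor_total": DEFAULT_RECEPTOR_TOTAL},
        provenance="default",
    )
    if initial_overrides:
        new_species = []
        for s in model.species:
            if s.name in initial_overrides:
                new_species.append(replace(s, initial=initial_overrides.pop(s.name)))
            else:
                new_species.append(s)
        if initial_overrides:
            raise ConfigurationError(
                f"unknown species in initial overrides: {sorted(initial_overrides)}")
        model.species = new_species
    return model


def build_inflammation_model(config: Mapping[str, float] | None = None) -> NetworkModel:
    """The antigen-driven variant used for the bistability/control analyses.

    Bacteria are removed from the computation (frozen at zero) and replaced
    by the constant cross-reactive-antigen influx ``v_CRA`` as the driver of
    inflammation; everything else is the default model. The invariant
    zero-bacteria direction would otherwise contribute a spurious positive
    eigenvalue to every stability call.
    """
    return freeze_species(build_default_model(config), "bacteria", 0.0)


# --------------------------------------------------------------------------- #
# analytic toy fixtures
# --------------------------------------------------------------------------- #

TOY_NAMES = ("decay", "switch1d", "toggle2d")

#: switch1d default constants; with these the scalar rate
#: b + beta*x^2/(K^2+x^2) - gamma*x has the exact fixed points {2, 3, 6}
#: (stable, unstable, stable) with derivatives -0.1, +1/15, -1/6 per min.
SWITCH1D_DEFAULTS = {"b": 1.0, "beta": 10.0, "K": 6.0, "gamma": 1.0}

TOGGLE2D_DEFAULTS = {"alpha": 4.0, "n": 2.0, "delta": 1.0}


def build_toy_model(name: str, **params: float) -> NetworkModel:
    """Build an analytic toy fixture: ``decay``, ``switch1d`` or ``toggle2d``.

    decay
        One species, dx/dt = v - k*x; fixed point x* = v/k, eigenvalue -k.
    switch1d
        One species with basal influx, cooperative positive feedback
        (Hill n=2) and first-order loss; bistable for the default constants,
        which give the exact fixed points 2 (stable), 3 (unstable), 6 (stable).
    toggle2d
        Symmetric mutual repression of two species; the symmetric state is a
        saddle whose stable manifold (the basin boundary) is the diagonal.
    """
    if name == "decay":
        p = {"v": 0.0, "k": 0.1}
        p.update(params)
        model = NetworkModel(
            species=[SpeciesSpec("x", initial=1.0)],
            reactions=[
                ReactionSpec("influx", {"x": +1},
                             RateLaw("zero_order_influx", {"rate": "v"}), "influx"),
                ReactionSpec("decay", {"x": -1},
                             RateLaw("first_order_washout", {"k": "k"}), "decay"),
            ],
            parameters={"v": float(p["v"]), "k": float(p["k"])},
            provenance="toy:decay",
        )
        return model
    if name == "switch1d":
        p = dict(SWITCH1D_DEFAULTS)
        p.update(params)
        model = NetworkModel(
            species=[SpeciesSpec("x", initial=0.0)],
            reactions=[
                ReactionSpec("basal influx", {"x": +1},
                             RateLaw("zero_order_influx", {"rate": "b"}), "basal_influx"),
                ReactionSpec("positive feedback", {"x": +1},
                             RateLaw("saturable", {"k": "beta", "K": "K", "n": "n_hill"},
                                     species={"stimulus": "x"},
                                     modifier_species=("x",)),
                             "feedback"),
                ReactionSpec("loss", {"x": -1},
                             RateLaw("first_order_washout", {"k": "gamma"}), "loss"),
            ],
            parameters={"b": float(p["b"]), "beta": float(p["beta"]),
                        "K": float(p["K"]), "gamma": float(p["gamma"]),
                        "n_hill": 2.0},
            provenance="toy:switch1d",
        )
        return model
    if name == "toggle2d":
        p = dict(TOGGLE2D_DEFAULTS)
        p.update(params)
        alpha, n, delta = float(p["alpha"]), float(p["n"]), float(p["delta"])

        def repress_y(state, prm):
            return prm["alpha"] / (1.0 + state["y"] ** prm["n_hill"])

        def repress_x(state, prm):
            return prm["alpha"] / (1.0 + state["x"] ** prm["n_hill"])

        model = NetworkModel(
            species=[SpeciesSpec("x", initial=2.0), SpeciesSpec("y", initial=0.1)],
            reactions=[
                ReactionSpec("production of x", {"x": +1},
                             RateLaw("expression", expression=repress_y,
                                     modifier_species=("y",)),
                             "x_production"),
                ReactionSpec("loss of x", {"x": -1},
                             RateLaw("first_order_washout", {"k": "delta"}), "x_loss"),
                ReactionSpec("production of y", {"y": +1},
                             RateLaw("expression", expression=repress_x,
                                     modifier_species=("x",)),
                             "y_production"),
                ReactionSpec("loss of y", {"y": -1},
                             RateLaw("first_order_washout", {"k": "delta"}), "y_loss"),
            ],
            parameters={"alpha": alpha, "n_hill": n, "delta": delta},
            provenance="toy:toggle2d",
        )
        return model
    raise ConfigurationError(
        f"unknown toy model {name!r}; available fixtures: {', '.join(TOY_NAMES)}")


def switch1d_fixed_points(model: NetworkModel,
                          x_max: float = 100.0, n_grid: int = 20000) -> list[float]:
    """Dense 1-D root bracketing of the switch1d scalar rate (the oracle).

    Returns all roots of dx/dt on [0, x_max], refined by bisection.
    """
    from scipy.optimize import brentq

    def f(x: float) -> float:
        return float(model.rhs(0.0, np.array([x]))[0])

    xs = np.linspace(0.0, x_max, n_grid)
    vals = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append(xs[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-12))
    # dedupe near-identical roots
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-8 * max(1.0, abs(r)):
            out.append(r)
    return out


# --------------------------------------------------------------------------- #
# freezing
# --------------------------------------------------------------------------- #

def freeze_species(model: NetworkModel, species_name: str, value: float) -> NetworkModel:
    """Clamp a species to ``value``: its derivative is removed but it keeps
    appearing in all rate laws at the clamped concentration."""
    if species_name not in model.species_names:
        raise ConfigurationError(f"unknown species {species_name!r}")
    m = model.copy()
    m.frozen[species_name] = float(value)
    return m
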