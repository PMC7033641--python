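"""Minimal SBML Level 2/3 import (read-only).

Parses species, global/local parameters and reactions with explicit kinetic
laws into a :class:`~innatedyn.network_model.NetworkModel`. Kinetic-law
content MathML is translated into sympy expressions and compiled.

Supported: a single well-mixed compartment, irreversible or reversible
reactions with kinetic laws, boundary/constant species, local kinetic-law
parameters (namespaced ``<reaction id>.<parameter id>``).

Not supported (explicit errors, never silent skips): events, algebraic /
assignment / rate rules, function definitions, multiple compartments,
reactions without kinetic laws.

Concentrations and rate constants are taken at the file's face value and
interpreted on the package's canonical scale (fM, min); files written on a
different scale should be converted before import.
"""

from __future__ import annotations

from typing import Mapping

import sympy as sp
from lxml import etree

from .network_model import NetworkModel, RateLaw, ReactionSpec, SpeciesSpec

__all__ = ["load_sbml", "SBMLImportError", "UnsupportedSBMLError"]


class SBMLImportError(ValueError):
    """The file is not importable (missing kinetic law, malformed math, ...)."""


class UnsupportedSBMLError(SBMLImportError):
    """The file uses an SBML construct outside the supported subset."""


_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(tag: str) -> str:
    return tag.split("}", 1)[-1]


def _mathml_to_sympy(node, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLImportError("MathML <math> must contain one expression")
        return _mathml_to_sympy(children[0], symbols)
    if tag == "ci":
        name = node.text.strip()
        return symbols.setdefault(name, sp.Symbol(name))
    if tag == "cn":
        ctype = node.get("type", "real")
        if ctype in ("real", "integer", "double"):
            return sp.Float(node.text.strip())
        if ctype == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            if len(parts) != 2:
                raise SBMLImportError("malformed e-notation <cn>")
            return sp.Float(f"{parts[0]}e{parts[1]}")
        if ctype == "rational":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return sp.Rational(int(parts[0]), int(parts[1]))
        raise UnsupportedSBMLError(f"<cn type={ctype!r}> not supported")
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_mathml_to_sympy(c, symbols) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args) if args else sp.Integer(0)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "times":
            return sp.Mul(*args) if args else sp.Integer(1)
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "root":
            return sp.sqrt(args[0]) if len(args) == 1 else args[-1] ** (1 / args[0])
        if op == "exp":
            return sp.exp(args[0])
        if op == "ln":
            return sp.log(args[0])
        if op == "log":
            return sp.log(args[-1], 10)
        raise UnsupportedSBMLError(f"MathML operator <{op}> not supported")
    raise UnsupportedSBMLError(f"MathML element <{tag}> not supported")


def _find(parent, name):
    return [el for el in parent.iter() if isinstance(el.tag, str)
            and _local(el.tag) == name]


def load_sbml(path, process_tags: Mapping[str, str] | None = None) -> NetworkModel:
    """Import an SBML file into a :class:`NetworkModel`.

    ``process_tags`` optionally maps reaction ids to process-tag labels for
    the control analysis (the documented mapping table); by default the
    reaction id is used as its own tag.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    models = _find(root, "model")
    if not models:
        raise SBMLImportError("no <model> element")
    model_el = models[0]

    for bad, label in (("listOfEvents", "events"),
                       ("algebraicRule", "algebraic rules"),
                       ("rateRule", "rate rules"),
                       ("assignmentRule", "assignment rules"),
                       ("listOfFunctionDefinitions", "function definitions")):
        if _find(model_el, bad):
            raise UnsupportedSBMLError(f"SBML {label} are not supported")

    compartments = _find(model_el, "compartment")
    if len(compartments) > 1:
        raise UnsupportedSBMLError("multiple compartments are not supported")

    species_specs: list[SpeciesSpec] = []
    for s in _find(model_el, "species"):
        sid = s.get("id")
        init = s.get("initialConcentration", s.get("initialAmount", "0"))
        constant = (s.get("boundaryCondition", "false") == "true"
                    or s.get("constant", "false") == "true")
        species_specs.append(SpeciesSpec(sid, initial=float(init),
                                         constant=constant))
    species_ids = {s.name for s in species_specs}

    parameters: dict[str, float] = {}
    for p in _find(model_el, "listOfParameters"):
        if _local(p.getparent().tag) != "model":
            continue
        for el in p:
            if isinstance(el.tag, str) and _local(el.tag) == "parameter":
                parameters[el.get("id")] = float(el.get("value", "nan"))

    reactions: list[ReactionSpec] = []
    for r in _find(model_el, "reaction"):
        rid = r.get("id")
        stoich: dict[str, float] = {}
        modifiers: list[str] = []
        for lo in r:
            if not isinstance(lo.tag, str):
                continue
            kind = _local(lo.tag)
            if kind in ("listOfReactants", "listOfProducts"):
                sign = -1.0 if kind == "listOfReactants" else 1.0
                for ref in lo:
                    if isinstance(ref.tag, str) and _local(ref.tag) == "speciesReference":
                        coeff = float(ref.get("stoichiometry", "1"))
                        sp_id = ref.get("species")
                        stoich[sp_id] = stoich.get(sp_id, 0.0) + sign * coeff
            elif kind == "listOfModifiers":
                for ref in lo:
                    if isinstance(ref.tag, str):
                        modifiers.append(ref.get("species"))
        klaws = _find(r, "kineticLaw")
        if not klaws:
            raise SBMLImportError(f"reaction {rid!r} has no kinetic law")
        klaw = klaws[0]
        # local parameters, namespaced with the reaction id
        local_rename: dict[str, str] = {}
        for el in klaw.iter():
            if isinstance(el.tag, str) and _local(el.tag) in ("parameter",
                                                              "localParameter"):
                lid = el.get("id")
                gname = f"{rid}.{lid}"
                parameters[gname] = float(el.get("value", "nan"))
                local_rename[lid] = gname
        maths = [el for el in klaw if isinstance(el.tag, str)
                 and _local(el.tag) == "math"]
        if not maths:
            raise SBMLImportError(f"reaction {rid!r}: kinetic law has no <math>")
        symbols: dict[str, sp.Symbol] = {}
        expr = _mathml_to_sympy(maths[0], symbols)
        if local_rename:
            expr = expr.subs({sp.Symbol(k): sp.Symbol(v)
                              for k, v in local_rename.items()})
            symbols = {str(s): s for s in expr.free_symbols}
        free = sorted(str(s) for s in expr.free_symbols)
        comp_ids = {c.get("id") for c in compartments}
        for name in free:
            if name not in species_ids and name not in parameters \
                    and name not in comp_ids:
                raise SBMLImportError(
                    f"reaction {rid!r}: unknown symbol {name!r} in kinetic law")
        # compartments of size 1 drop out; other sizes scale the rate
        comp_size = float(compartments[0].get("size", "1")) if compartments else 1.0
        args = [sp.Symbol(n) for n in free]
        fn = sp.lambdify(args, expr, modules="math")

        def rate(state, prm, fn=fn, free=tuple(free), comp_ids=frozenset(comp_ids),
                 comp_size=comp_size, species_ids=frozenset(species_ids)):
            vals = []
            for name in free:
                if name in species_ids:
                    vals.append(state[name])
                elif name in comp_ids:
                    vals.append(comp_size)
                else:
                    vals.append(prm[name])
            return fn(*vals)

        tag = (process_tags or {}).get(rid, rid)
        reactions.append(ReactionSpec(
            rid, stoich,
            RateLaw("expression", expression=rate,
                    modifier_species=tuple(m for m in modifiers)),
            tag))

    return NetworkModel(species=species_specs, reactions=reactions,
                        parameters=parameters, provenance=f"sbml:{path}")
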