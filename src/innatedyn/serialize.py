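"""Human-readable model definition files (YAML) with documented round-trip.

Only structured rate laws round-trip; models containing compiled
``expression`` rate laws (SBML imports, the 2-D toggle fixture) cannot be
serialised and raise :class:`SerializationError`.
"""

from __future__ import annotations

import yaml

from .network_model import (NetworkModel, RateLaw, ReactionSpec, SpeciesSpec)

__all__ = ["model_to_yaml", "model_from_yaml", "SerializationError"]


class SerializationError(ValueError):
    pass


def model_to_dict(model: NetworkModel) -> dict:
    for r in model.reactions:
        if r.rate_law.form == "expression":
            raise SerializationError(
                f"reaction {r.name!r} uses a compiled expression rate law "
                "and cannot be serialised")
    return {
        "provenance": model.provenance,
        "species": [
            {"name": s.name, "unit": s.unit, "role": s.role, "floor": s.floor,
             "constant": s.constant, "initial": s.initial}
            for s in model.species],
        "reactions": [
            {"name": r.name,
             "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
             "process_tag": r.process_tag,
             "rate_law": {
                 "form": r.rate_law.form,
                 "parameters": dict(r.rate_law.parameters),
                 "species": dict(r.rate_law.species),
                 "modifier_species": list(r.rate_law.modifier_species)}}
            for r in model.reactions],
        "parameters": {k: float(v) for k, v in model.parameters.items()},
        "constants": {k: float(v) for k, v in model.constants.items()},
        "frozen": {k: float(v) for k, v in model.frozen.items()},
    }


def model_from_dict(data: dict) -> NetworkModel:
    species = [SpeciesSpec(**s) for s in data["species"]]
    reactions = [
        ReactionSpec(
            name=r["name"], stoichiometry=r["stoichiometry"],
            process_tag=r["process_tag"],
            rate_law=RateLaw(
                form=r["rate_law"]["form"],
                parameters=r["rate_law"]["parameters"],
                species=r["rate_law"]["species"],
                modifier_species=tuple(r["rate_law"]["modifier_species"])))
        for r in data["reactions"]]
    return NetworkModel(species=species, reactions=reactions,
                        parameters=dict(data["parameters"]),
                        constants=dict(data.get("constants", {})),
                        frozen=dict(data.get("frozen", {})),
                        provenance=data.get("provenance", "file"))


def model_to_yaml(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def model_from_yaml(path) -> NetworkModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
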