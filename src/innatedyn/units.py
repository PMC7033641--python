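"""Concentration unit handling.

All internal state is kept in femtomolar (fM) and time in minutes. Interfaces
accept/report attomolar through nanomolar; conversion factors are exact powers
of 10**3 relative to fM.
"""

from __future__ import annotations

#: multiplicative factor converting 1 unit of the key into fM
TO_FM = {
    "aM": 1e-3,
    "fM": 1.0,
    "pM": 1e3,
    "nM": 1e6,
}


def to_fm(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to fM."""
    try:
        return value * TO_FM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; known: {sorted(TO_FM)}")


def from_fm(value_fm: float, unit: str) -> float:
    """Convert a fM value to ``unit``."""
    try:
        return value_fm / TO_FM[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; known: {sorted(TO_FM)}")
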