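"""Lattice-unit <-> SI conversion ("mlt" framework).

With dx = dt = 1 in lattice units, a quantity with length exponent b and
time exponent c converts as value_SI = value_lu * dx^b * dt^c.  The rows
implemented here are the ones the permeability workflow needs; permeability
scales as dx^2 and is independent of dt.  1 darcy = 9.869233e-13 m^2.
"""

from __future__ import annotations

__all__ = ["convert_units", "DARCY_M2", "to_darcy"]

DARCY_M2 = 9.869233e-13

# kind -> (length exponent, time exponent)
_EXPONENTS = {
    "length": (1, 0),
    "time": (0, 1),
    "velocity": (1, -1),
    "kinematic_viscosity": (2, -1),
    "permeability": (2, 0),
}


def convert_units(value: float, kind: str, dx: float, dt: float = 1.0) -> float:
    """Convert ``value`` from lattice units to SI given dx [m] and dt [s]."""
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    try:
        b, c = _EXPONENTS[kind]
    except KeyError:
        raise ValueError(
            f"unknown kind {kind!r}; expected one of {sorted(_EXPONENTS)}"
        ) from None
    return value * dx ** b * dt ** c


def to_darcy(k_si: float) -> float:
    """Permeability in darcy from m^2."""
    return k_si / DARCY_M2
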