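"""Standard atomic weights, pinned so descriptor values are reproducible.

Values are the conventional (abridged) standard atomic weights in unified
atomic mass units. The table is intentionally frozen in-repo rather than
taken from a chemistry toolkit at run time, so the same structure always
yields the same mass-weighted descriptor values.
"""

from __future__ import annotations

# CIAAW standard atomic weights (abridged to 4-5 significant figures).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.098,
    "Ca": 40.078,
    "Ti": 47.867,
    "Cr": 51.996,
    "Mn": 54.938,
    "Fe": 55.845,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.38,
    "As": 74.922,
    "Se": 78.971,
    "Br": 79.904,
    "Mo": 95.95,
    "Ag": 107.87,
    "Sn": 118.71,
    "I": 126.90,
    "Pt": 195.08,
    "Au": 196.97,
    "Hg": 200.59,
    "Pb": 207.2,
}

#: mass of carbon, the conventional normalizer for mass-weighted descriptors
CARBON_MASS: float = ATOMIC_MASSES["C"]


class UnknownElementError(KeyError):
    """Element symbol not present in the pinned mass table."""


def atomic_mass(symbol: str) -> float:
    """Return the standard atomic weight of ``symbol`` in amu."""
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} is not in the pinned atomic-mass table"
        ) from None
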