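"""Embedded element reference data.

A single fixed table keeps every derived quantity (m/z, heteroatom counts,
surface areas, projection areas) reproducible across machines: monoisotopic
masses from the standard isotope compilation, van der Waals radii from the
Bondi set.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the embedded table."""


@dataclass(frozen=True)
class ElementData:
    """Reference data for one element.

    Attributes
    ----------
    symbol : str
        Chemical symbol (e.g. ``"C"``).
    monoisotopic_mass : float
        Mass of the most abundant isotope, Da.
    vdw_radius : float
        Bondi van der Waals radius, Angstrom.
    is_heteroatom : bool
        True for every element other than carbon and hydrogen.
    """

    symbol: str
    monoisotopic_mass: float
    vdw_radius: float
    is_heteroatom: bool


#: Mass of a proton, Da.  Used for the [M-H]- m/z; electron mass neglected.
PROTON_MASS = 1.00728

_TABLE = {
    #  symbol: (monoisotopic mass / Da, Bondi vdW radius / A)
    "H": (1.007825, 1.20),
    "C": (12.000000, 1.70),
    "N": (14.003074, 1.55),
    "O": (15.994915, 1.52),
    "F": (18.998403, 1.47),
    "P": (30.973762, 1.80),
    "S": (31.972071, 1.80),
    "Cl": (34.968853, 1.75),
}

ELEMENTS: dict[str, ElementData] = {
    sym: ElementData(sym, mass, radius, sym not in ("C", "H"))
    for sym, (mass, radius) in _TABLE.items()
}


def element_lookup(symbol: str) -> ElementData:
    """Return the :class:`ElementData` for *symbol*.

    Raises
    ------
    UnknownElementError
        If the symbol is not in the embedded table.
    """
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise UnknownElementError(
            f"unknown element symbol {symbol!r}; known: {sorted(ELEMENTS)}"
        ) from None
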