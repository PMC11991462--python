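"""Element table: atomic numbers, standard atomic weights and K-edge energies.

The package works with the twelve elements that occur in the six study
materials (PEEK, bone, and PEEK composites with BaSO4, Ta, Bi2O3 and
hydroxyapatite).  Atomic weights are IUPAC standard values.  K-shell binding
energies are stored only when they fall inside the photon-data grid used by
the package (above ~10 keV); lighter elements carry ``k_edge = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import LookupError_

__all__ = ["Element", "ELEMENTS", "get_element"]


@dataclass(frozen=True)
class Element:
    """A chemical element.

    Attributes
    ----------
    symbol : str
        Chemical symbol, e.g. ``"Ba"``.
    Z : int
        Atomic number.
    A : float
        Standard atomic weight, g/mol.
    k_edge : float
        K-shell binding energy in keV, or 0 when the edge lies below the
        tabulated energy grid and is therefore not modelled.
    """

    symbol: str
    Z: int
    A: float
    k_edge: float = 0.0

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if self.k_edge < 0:
            raise ValueError(f"k_edge must be >= 0, got {self.k_edge}")


# K-edges for Ba and Ta are the values conventionally quoted for diagnostic
# imaging (37.4 and 67.4 keV); Bi uses the standard 90.5 keV.  Lighter
# elements (Z <= 20) have K-edges below 10 keV, outside the modelled grid.
ELEMENTS: dict[str, Element] = {
    "H": Element("H", 1, 1.008),
    "C": Element("C", 6, 12.011),
    "N": Element("N", 7, 14.007),
    "O": Element("O", 8, 15.999),
    "Na": Element("Na", 11, 22.990),
    "Mg": Element("Mg", 12, 24.305),
    "P": Element("P", 15, 30.974),
    "S": Element("S", 16, 32.06),
    "Ca": Element("Ca", 20, 40.078),
    "Ba": Element("Ba", 56, 137.327, k_edge=37.4),
    "Ta": Element("Ta", 73, 180.948, k_edge=67.4),
    "Bi": Element("Bi", 83, 208.980, k_edge=90.5),
}


def get_element(symbol: str) -> Element:
    """Return the :class:`Element` for *symbol*, raising on unknown symbols."""
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise LookupError_(f"unknown element symbol {symbol!r}") from None
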