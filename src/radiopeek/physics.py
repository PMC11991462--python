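"""Per-element photon physics: Klein-Nishina scattering, parameterized
photoelectric and coherent mass coefficients, energy grids and log-log
interpolation.

The photoatomic model is deliberately simple and fully self-consistent
across the package:

* photoelectric: per-element two-branch power law with a discontinuous
  upward jump at the K edge (anchor constants embedded in
  :mod:`radiopeek._fixture_constants`);
* incoherent: free-electron Klein-Nishina cross-section times the electron
  density Z/A of the element (no incoherent scattering function);
* coherent: per-element power law, included by default and toggleable.

All energies are keV, mass coefficients cm2/g, cross-sections cm2 per atom
or per electron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fixture_constants as _fc
from .elements import ELEMENTS, Element, get_element
from .errors import DomainError, LookupError_, RangeError

__all__ = [
    "N_AVOGADRO",
    "ELECTRON_REST_KEV",
    "R_E_CM",
    "kn_total_cross_section",
    "kn_differential",
    "compton_scattered_energy",
    "photoelectric_mass_coeff",
    "coherent_mass_coeff",
    "incoherent_mass_coeff",
    "element_mass_attenuation",
    "EnergyGrid",
    "ElementPhotonTable",
    "PhotonDataLibrary",
    "interpolate_log_log",
]

N_AVOGADRO = 6.02214076e23  # 1/mol
ELECTRON_REST_KEV = 510.99895  # m_e c^2 in keV
R_E_CM = 2.8179403262e-13  # classical electron radius, cm


# ---------------------------------------------------------------------------
# Klein-Nishina
# ---------------------------------------------------------------------------

def kn_total_cross_section(energy_kev):
    """Total Klein-Nishina cross-section per free electron (cm2).

    Closed form in the reduced energy ``k = E / m_e c^2``; tends to the
    Thomson cross-section (0.6652 barn) as E -> 0.
    """
    E = np.asarray(energy_kev, dtype=float)
    if np.any(E <= 0):
        raise DomainError("photon energy must be > 0 keV")
    k = E / ELECTRON_REST_KEV
    lg = np.log1p(2.0 * k)
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - lg / k)
    term2 = lg / (2.0 * k)
    term3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    sigma = 2.0 * np.pi * R_E_CM**2 * (term1 + term2 - term3)
    return sigma if sigma.ndim else float(sigma)


def compton_scattered_energy(energy_kev, theta):
    """Compton-shifted photon energy E' at scattering angle theta (radians)."""
    E = np.asarray(energy_kev, dtype=float)
    k = E / ELECTRON_REST_KEV
    out = E / (1.0 + k * (1.0 - np.cos(theta)))
    return out if out.ndim else float(out)


def kn_differential(energy_kev, theta):
    """Klein-Nishina differential cross-section dsigma/dOmega (cm2/sr/electron).

    ``theta`` must lie in [0, pi].
    """
    E = np.asarray(energy_kev, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(E <= 0):
        raise DomainError("photon energy must be > 0 keV")
    if np.any((th < 0) | (th > np.pi)):
        raise DomainError("scattering angle must lie in [0, pi]")
    ratio = compton_scattered_energy(E, th) / E  # E'/E
    out = 0.5 * R_E_CM**2 * ratio**2 * (ratio + 1.0 / ratio - np.sin(th) ** 2)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Parameterized per-element coefficients
# ---------------------------------------------------------------------------

def _power_law(anchors, energy):
    """Evaluate the power law through two (E, value) anchor points."""
    (e1, v1), (e2, v2) = anchors
    p = np.log(v2 / v1) / np.log(e2 / e1)
    return v1 * (np.asarray(energy, dtype=float) / e1) ** p


def _as_element(element) -> Element:
    return element if isinstance(element, Element) else get_element(element)


def photoelectric_mass_coeff(element, energy_kev):
    """Photoelectric mass attenuation coefficient (cm2/g).

    Piecewise power law with a discontinuous upward jump at the element's
    K edge; energies exactly at the edge evaluate on the above-edge branch.
    """
    el = _as_element(element)
    E = np.asarray(energy_kev, dtype=float)
    if np.any(E < _fc.LIBRARY_EMIN) or np.any(E > _fc.LIBRARY_EMAX):
        raise RangeError(
            f"energy outside library validity range "
            f"[{_fc.LIBRARY_EMIN}, {_fc.LIBRARY_EMAX}] keV"
        )
    try:
        spec = _fc.PHOTOELECTRIC_ANCHORS[el.symbol]
    except KeyError:
        raise LookupError_(f"no photoelectric anchors for {el.symbol!r}") from None
    if "pe" in spec:
        out = _power_law(spec["pe"], E)
    else:
        below = _power_law(spec["pe_below"], E)
        above = _power_law(spec["pe_above"], E)
        out = np.where(E >= el.k_edge, above, below)
    return out if np.ndim(out) else float(out)


def coherent_mass_coeff(element, energy_kev):
    """Coherent (Rayleigh) mass attenuation coefficient (cm2/g)."""
    el = _as_element(element)
    out = _power_law(_fc.COHERENT_ANCHORS[el.symbol], np.asarray(energy_kev, float))
    return out if np.ndim(out) else float(out)


def incoherent_mass_coeff(element, energy_kev):
    """Incoherent mass coefficient (cm2/g): (Z/A) N_A sigma_KN(E)."""
    el = _as_element(element)
    out = el.Z / el.A * N_AVOGADRO * kn_total_cross_section(energy_kev)
    return out if np.ndim(out) else float(out)


def element_mass_attenuation(element, energy_kev, include_coherent=True):
    """Total elemental mass attenuation coefficient (cm2/g).

    Sum of the photoelectric, Klein-Nishina incoherent and (optionally)
    coherent terms; identical to the sum of the per-process columns of the
    generated :class:`ElementPhotonTable` at every grid node.
    """
    el = _as_element(element)
    total = photoelectric_mass_coeff(el, energy_kev) + incoherent_mass_coeff(
        el, energy_kev
    )
    if include_coherent:
        total = total + coherent_mass_coeff(el, energy_kev)
    return total if np.ndim(total) else float(total)


# ---------------------------------------------------------------------------
# Grids, tables, interpolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyGrid:
    """A photon-energy grid (keV), non-decreasing, with optional duplicated
    nodes bracketing K-edge discontinuities (below/above values).
    """

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 2:
            raise DomainError("energy grid must be a 1-D array of >= 2 energies")
        if e[0] < 1.0:
            raise DomainError("energy grid must start at >= 1 keV")
        d = np.diff(e)
        if np.any(d < 0):
            raise DomainError("energy grid must be non-decreasing")
        # duplicates are only allowed as isolated pairs (edge nodes)
        dup = np.flatnonzero(d == 0)
        if np.any(np.diff(dup) == 1):
            raise DomainError("grid nodes may be duplicated at most once")

    @classmethod
    def diagnostic(cls, emin=20.0, emax=120.0, step=0.1, edges=None) -> "EnergyGrid":
        """The standard study grid: [emin, emax] at *step* keV with duplicated
        nodes at every K edge in range.

        ``edges=None`` inserts the K edges of all library elements.
        """
        n = int(round((emax - emin) / step))
        e = emin + step * np.arange(n + 1)
        if edges is None:
            edges = [el.k_edge for el in ELEMENTS.values() if el.k_edge > 0]
        ins = [k for k in edges if emin < k < emax]
        e = np.round(np.sort(np.concatenate([e, ins, ins])), 9)
        # collapse accidental triplicates when an edge sits on a grid node
        keep = np.ones(e.size, dtype=bool)
        run = 1
        for i in range(1, e.size):
            run = run + 1 if e[i] == e[i - 1] else 1
            if run > 2:
                keep[i] = False
        return cls(e[keep])

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])

    def __len__(self) -> int:
        return self.energies.size


def interpolate_log_log(grid_energies, values, energy_kev):
    """Log-log linear interpolation honouring duplicated edge nodes.

    Queries exactly at a duplicated node return the above-edge value, per
    the package convention.  Queries outside the grid span raise
    :class:`RangeError`.
    """
    x = np.asarray(grid_energies, dtype=float)
    y = np.asarray(values, dtype=float)
    q = np.asarray(energy_kev, dtype=float)
    if np.any(q < x[0]) or np.any(q > x[-1]):
        raise RangeError("interpolation query outside grid span")
    idx = np.searchsorted(x, q, side="right")
    lo = np.clip(idx - 1, 0, x.size - 1)
    hi = np.clip(idx, 0, x.size - 1)
    exact = x[lo] == q
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (np.log(q) - np.log(x[lo])) / (np.log(x[hi]) - np.log(x[lo]))
        interp = np.exp(np.log(y[lo]) + t * (np.log(y[hi]) - np.log(y[lo])))
    out = np.where(exact, y[lo], interp)
    return out if np.ndim(out) else float(out)


@dataclass
class ElementPhotonTable:
    """Per-element per-process mass coefficients on an energy grid."""

    element: Element
    grid: EnergyGrid
    pe: np.ndarray
    incoh: np.ndarray
    coh: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pe", "incoh", "coh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.grid.energies.shape:
                raise DomainError(f"{name} column does not match grid shape")
            if np.any(arr <= 0):
                raise DomainError(f"{name} column must be strictly positive")

    def total(self, include_coherent: bool = True) -> np.ndarray:
        out = self.pe + self.incoh
        if include_coherent:
            out = out + self.coh
        return out

    def interp(self, energy_kev, process: str = "total", include_coherent=True):
        """Log-log interpolate a process column ('pe'|'incoh'|'coh'|'total')."""
        col = (
            self.total(include_coherent)
            if process == "total"
            else getattr(self, process)
        )
        return interpolate_log_log(self.grid.energies, col, energy_kev)


@dataclass
class PhotonDataLibrary:
    """Per-element photon tables plus a fixture version tag.

    Built by :func:`radiopeek.synthetic.build_default_library`; the
    analytic parameterization functions above evaluate identically to the
    stored tables at every grid node.
    """

    tables: dict[str, ElementPhotonTable]
    version: str = _fc.FIXTURE_VERSION

    REQUIRED = ("H", "C", "N", "O", "Na", "Mg", "P", "S", "Ca", "Ba", "Ta", "Bi")

    def __post_init__(self) -> None:
        missing = [s for s in self.REQUIRED if s not in self.tables]
        if missing:
            raise DomainError(f"library missing required elements: {missing}")

    def __getitem__(self, symbol: str) -> ElementPhotonTable:
        try:
            return self.tables[symbol]
        except KeyError:
            raise LookupError_(f"element {symbol!r} not in library") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.tables

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: (element, energy_keV, pe, incoh, coh)."""
        parts = []
        for sym, tab in self.tables.items():
            parts.append(
                pd.DataFrame(
                    {
                        "element": sym,
                        "energy_keV": tab.grid.energies,
                        "pe": tab.pe,
                        "incoh": tab.incoh,
                        "coh": tab.coh,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def elements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "symbol": s,
                    "Z": t.element.Z,
                    "A": t.element.A,
                    "k_edge_keV": t.element.k_edge,
                }
                for s, t in self.tables.items()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
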