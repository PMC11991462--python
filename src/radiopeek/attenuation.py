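"""Material-level photon-interaction parameters.

Everything the radiopacity assessment needs per material: mass and linear
attenuation coefficients, transmission, half-value layer, total atomic and
electronic cross-sections, effective atomic number Z_eff, effective electron
density N_eff, percent increase over a baseline, and K-edge localization.

Definitions
-----------
* ``mu_m = sum_i w_i (mu/rho)_i``   (weight-fraction mixture rule)
* ``mu = mu_m rho``;  ``I/I0 = exp(-mu x)``;  ``HVL = ln2 / mu``
* ``sigma_t,a = mu_m / (N_A sum_i w_i/A_i)``      (cm2/atom)
* ``sigma_t,el = (1/N_A) sum_i f_i (A_i/Z_i) (mu/rho)_i``  (cm2/electron)
* ``Z_eff = sigma_t,a / sigma_t,el``;  ``N_eff = mu_m / sigma_t,el``

For a pure element these collapse to ``Z_eff = Z`` and
``N_eff = N_A Z / A`` exactly, which is the package's main internal check
of the cross-section formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elements import get_element
from .errors import DomainError, ResolutionError
from .materials import Material, atom_fractions
from .physics import (
    N_AVOGADRO,
    EnergyGrid,
    PhotonDataLibrary,
    coherent_mass_coeff,
    element_mass_attenuation,
    incoherent_mass_coeff,
    photoelectric_mass_coeff,
)

__all__ = [
    "AttenuationCurve",
    "mixture_mu_m",
    "mixture_process_coeffs",
    "linear_mu",
    "transmission",
    "hvl",
    "total_atomic_cross_section",
    "total_electronic_cross_section",
    "z_eff",
    "n_eff",
    "percent_increase",
    "compute_curve",
    "locate_k_edge",
]


def _element_mu(symbol, energy, include_coherent, library):
    if library is None:
        return element_mass_attenuation(symbol, energy, include_coherent)
    return library[symbol].interp(energy, "total", include_coherent)


def mixture_mu_m(
    material: Material,
    energy_kev,
    include_coherent: bool = True,
    library: PhotonDataLibrary | None = None,
):
    """Mass attenuation coefficient of a material (cm2/g).

    Weight-fraction-weighted sum of the elemental coefficients, evaluated
    from the packaged parameterization (or from *library* tables by log-log
    interpolation when one is supplied).
    """
    E = np.asarray(energy_kev, dtype=float)
    out = sum(
        w * _element_mu(sym, E, include_coherent, library)
        for sym, w in material.composition.items()
    )
    return out if np.ndim(out) else float(out)


def mixture_process_coeffs(
    material: Material, energy_kev, include_coherent: bool = True
) -> dict[str, np.ndarray]:
    """Per-process mass coefficients (cm2/g) of a material.

    Returns ``{"pe": ..., "incoh": ..., "coh": ...}``; the coherent entry is
    zero when *include_coherent* is false.  The transport module selects
    interaction types from exactly these coefficients, which keeps the Monte
    Carlo totals identical to the attenuation totals.
    """
    E = np.asarray(energy_kev, dtype=float)
    pe = sum(w * photoelectric_mass_coeff(s, E) for s, w in material.composition.items())
    incoh = sum(w * incoherent_mass_coeff(s, E) for s, w in material.composition.items())
    if include_coherent:
        coh = sum(w * coherent_mass_coeff(s, E) for s, w in material.composition.items())
    else:
        coh = np.zeros_like(E)
    return {"pe": pe, "incoh": incoh, "coh": coh}


def linear_mu(material: Material, energy_kev, include_coherent=True, library=None):
    """Linear attenuation coefficient mu = mu_m * rho (1/cm)."""
    return mixture_mu_m(material, energy_kev, include_coherent, library) * material.density


def transmission(mu, x):
    """Fractional transmitted intensity I/I0 = exp(-mu x) through x cm."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("thickness must be >= 0")
    out = np.exp(-np.asarray(mu, dtype=float) * x)
    return out if np.ndim(out) else float(out)


def hvl(mu):
    """Half-value layer ln2/mu (cm)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise DomainError("mu must be > 0")
    out = np.log(2.0) / mu
    return out if np.ndim(out) else float(out)


def _atoms_per_gram(material: Material) -> float:
    return N_AVOGADRO * sum(
        w / get_element(s).A for s, w in material.composition.items()
    )


def total_atomic_cross_section(
    material: Material, energy_kev, include_coherent=True, library=None
):
    """Total atomic cross-section sigma_t,a = mu_m / (N_A sum w_i/A_i), cm2/atom."""
    mu_m = mixture_mu_m(material, energy_kev, include_coherent, library)
    return mu_m / _atoms_per_gram(material)


def total_electronic_cross_section(
    material: Material, energy_kev, include_coherent=True, library=None
):
    """Total electronic cross-section (cm2/electron).

    ``sigma_t,el = (1/N_A) sum_i f_i (A_i/Z_i) (mu/rho)_i`` with f_i the
    atom fractions of the composition.
    """
    E = np.asarray(energy_kev, dtype=float)
    fr = atom_fractions(material.composition)
    out = sum(
        f * get_element(s).A / get_element(s).Z
        * _element_mu(s, E, include_coherent, library)
        for s, f in fr.items()
    ) / N_AVOGADRO
    return out if np.ndim(out) else float(out)


def z_eff(material: Material, energy_kev, include_coherent=True, library=None):
    """Effective atomic number: sigma_t,a / sigma_t,el (dimensionless)."""
    return total_atomic_cross_section(
        material, energy_kev, include_coherent, library
    ) / total_electronic_cross_section(material, energy_kev, include_coherent, library)


def n_eff(material: Material, energy_kev, include_coherent=True, library=None):
    """Effective electron density: mu_m / sigma_t,el (electrons/g)."""
    return mixture_mu_m(
        material, energy_kev, include_coherent, library
    ) / total_electronic_cross_section(material, energy_kev, include_coherent, library)


def percent_increase(mu_composite, mu_baseline):
    """Percent increase of a coefficient over a baseline: 100 (mu_c - mu_b)/mu_b."""
    mu_b = np.asarray(mu_baseline, dtype=float)
    if np.any(mu_b <= 0):
        raise DomainError("baseline coefficient must be > 0")
    out = 100.0 * (np.asarray(mu_composite, dtype=float) - mu_b) / mu_b
    return out if np.ndim(out) else float(out)


@dataclass
class AttenuationCurve:
    """All photon-interaction parameters of one material on an energy grid."""

    material: str
    grid: EnergyGrid
    mu_m: np.ndarray  # cm2/g
    mu: np.ndarray  # 1/cm
    hvl: np.ndarray  # cm
    z_eff: np.ndarray
    n_eff: np.ndarray  # electrons/g
    include_coherent: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "material": self.material,
                "energy_keV": self.grid.energies,
                "mu_m_cm2_g": self.mu_m,
                "mu_1_cm": self.mu,
                "hvl_cm": self.hvl,
                "z_eff": self.z_eff,
                "n_eff": self.n_eff,
            }
        )


def compute_curve(
    material: Material,
    grid: EnergyGrid | None = None,
    include_coherent: bool = True,
    library: PhotonDataLibrary | None = None,
) -> AttenuationCurve:
    """Evaluate the full attenuation curve of *material* on *grid*.

    Defaults to the diagnostic grid, 20-120 keV in 0.1 keV steps with
    duplicated nodes at in-range K edges.
    """
    if grid is None:
        grid = EnergyGrid.diagnostic()
    E = grid.energies
    mu_m = np.empty_like(E)
    zi = np.empty_like(E)
    ni = np.empty_like(E)
    # evaluate below-edge branch values on the first node of duplicated pairs
    dup_first = np.zeros(E.size, dtype=bool)
    dup_first[:-1] = E[:-1] == E[1:]
    for sel, eps in ((~dup_first, 0.0), (dup_first, -1e-9)):
        if not sel.any():
            continue
        Eq = E[sel] + eps
        mu_m[sel] = mixture_mu_m(material, Eq, include_coherent, library)
        zi[sel] = z_eff(material, Eq, include_coherent, library)
        ni[sel] = n_eff(material, Eq, include_coherent, library)
    mu = mu_m * material.density
    return AttenuationCurve(
        material=material.name,
        grid=grid,
        mu_m=mu_m,
        mu=mu,
        hvl=np.log(2.0) / mu,
        z_eff=zi,
        n_eff=ni,
        include_coherent=include_coherent,
    )


def locate_k_edge(curve: AttenuationCurve, rel_threshold: float = 0.05):
    """Locate the K-edge discontinuity of an attenuation curve.

    Returns the energy (keV) of the largest upward jump of ``mu_m`` between
    adjacent grid points, or ``None`` when no jump exceeds *rel_threshold*
    (relative).  Requires a grid step of at most 0.1 keV so the jump is not
    diluted across a wide interval.
    """
    E = curve.grid.energies
    steps = np.diff(E)
    distinct = steps[steps > 0]
    if distinct.size and distinct.max() > 0.1 + 1e-9:
        raise ResolutionError(
            "grid step must be <= 0.1 keV for K-edge localization"
        )
    rel_jump = np.diff(curve.mu_m) / curve.mu_m[:-1]
    i = int(np.argmax(rel_jump))
    if rel_jump[i] <= rel_threshold:
        return None
    return float(E[i + 1])
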