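"""Synthetic data and fixtures: the photon-data library builder, seeded test
images with known moments, and Beer-Lambert parameter-recovery experiments.

This module stands in for the study's external dependencies: the
photoatomic data library is generated deterministically from embedded
parameterization constants, and transmission-count experiments with known
attenuation coefficients close the loop between the transport and
attenuation halves of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _fixture_constants as _fc
from .elements import ELEMENTS, get_element
from .errors import DomainError, RadiopeekError
from .materials import Material
from .metrics import ProjectionMap
from .physics import (
    EnergyGrid,
    ElementPhotonTable,
    PhotonDataLibrary,
    incoherent_mass_coeff,
    _power_law,
)

__all__ = [
    "FixtureSpec",
    "build_default_library",
    "default_library",
    "make_test_image",
    "RecoveryExperiment",
    "RecoveryResult",
    "simulate_transmission_counts",
    "mu_recovery",
    "run_recovery",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameterization constants from which the photon-data fixture is built."""

    pe_anchors: dict = field(default_factory=lambda: _fc.PHOTOELECTRIC_ANCHORS)
    coh_anchors: dict = field(default_factory=lambda: _fc.COHERENT_ANCHORS)
    emin: float = _fc.LIBRARY_EMIN
    emax: float = _fc.LIBRARY_EMAX
    step: float = _fc.LIBRARY_STEP
    version: str = _fc.FIXTURE_VERSION


def build_default_library(spec: FixtureSpec | None = None) -> PhotonDataLibrary:
    """Generate the per-element photon tables from a :class:`FixtureSpec`.

    Deterministic for a given spec: the tables are evaluated from the anchor
    power laws on the standard grid (duplicated nodes at in-range K edges,
    the first of each pair holding the below-edge value).
    """
    spec = spec or FixtureSpec()
    edges = [el.k_edge for el in ELEMENTS.values()
             if spec.emin < el.k_edge < spec.emax]
    grid = EnergyGrid.diagnostic(spec.emin, spec.emax, spec.step, edges=edges)
    E = grid.energies
    dup_first = np.zeros(E.size, dtype=bool)
    dup_first[:-1] = E[:-1] == E[1:]

    tables: dict[str, ElementPhotonTable] = {}
    for sym, el in ELEMENTS.items():
        try:
            pe_spec = spec.pe_anchors[sym]
            coh_spec = spec.coh_anchors[sym]
        except KeyError:
            raise RadiopeekError(
                f"fixture spec is missing parameterization for element {sym!r}"
            ) from None
        if "pe" in pe_spec:
            pe = _power_law(pe_spec["pe"], E)
        else:
            below = _power_law(pe_spec["pe_below"], E)
            above = _power_law(pe_spec["pe_above"], E)
            pe = np.where(E >= el.k_edge, above, below)
            # first node of the duplicated K-edge pair carries the
            # below-edge limit so the jump is represented on the grid
            own_edge = dup_first & (E == el.k_edge)
            pe[own_edge] = below[own_edge]
        incoh = incoherent_mass_coeff(el, E)
        coh = _power_law(coh_spec, E)
        tables[sym] = ElementPhotonTable(el, grid, pe, incoh, coh)
    return PhotonDataLibrary(tables, version=spec.version)


_DEFAULT_LIBRARY: PhotonDataLibrary | None = None


def default_library() -> PhotonDataLibrary:
    """The packaged photon-data library, built once and cached."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = build_default_library()
    return _DEFAULT_LIBRARY


def make_test_image(
    n_pixels: int, mean: float, std: float, seed: int, poisson: bool = False
) -> ProjectionMap:
    """A seeded pseudo-random projection map with stated moments.

    Pixels are normal draws (mean, std) truncated at zero; the truncation
    rate is recorded in ``meta["truncation_rate"]``.  ``poisson=True``
    draws Poisson counts with the given mean instead (std ignored).
    """
    if std < 0:
        raise DomainError("std must be >= 0")
    rng = np.random.default_rng(seed)
    h = int(np.sqrt(n_pixels))
    while h > 1 and n_pixels % h:
        h -= 1
    w = n_pixels // h
    if poisson:
        vals = rng.poisson(mean, n_pixels).astype(float)
        rate = 0.0
    else:
        vals = rng.normal(mean, std, n_pixels) if std > 0 else np.full(n_pixels, mean)
        neg = vals < 0
        rate = float(neg.mean())
        vals[neg] = 0.0
    pm = ProjectionMap(
        plane="XY",
        pixels=vals.reshape(h, w),
        pixel_size=(1.0, 1.0),
        masks={"all": np.ones((h, w), dtype=bool)},
        meta={"truncation_rate": rate, "seed": seed},
    )
    return pm


@dataclass(frozen=True)
class RecoveryExperiment:
    """A transmission experiment with known linear attenuation coefficient."""

    material_name: str
    true_mu: float  # 1/cm
    thicknesses: tuple  # cm
    photons_per_thickness: int
    seed: int = 0

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.thicknesses):
            raise DomainError("thicknesses must be > 0")
        if self.photons_per_thickness < 1:
            raise DomainError("need photons_per_thickness >= 1")


@dataclass(frozen=True)
class RecoveryResult:
    mu: float
    ci_low: float
    ci_high: float
    stderr: float
    confidence: float
    n_points: int

    def covers(self, true_mu: float) -> bool:
        return self.ci_low <= true_mu <= self.ci_high


def simulate_transmission_counts(exp: RecoveryExperiment, rng=None) -> np.ndarray:
    """Binomial transmitted counts with survival probability exp(-mu x)."""
    rng = np.random.default_rng(exp.seed) if rng is None else rng
    p = np.exp(-exp.true_mu * np.asarray(exp.thicknesses))
    return rng.binomial(exp.photons_per_thickness, p).astype(float)


def mu_recovery(
    thicknesses, transmitted, incident, confidence: float = 0.99
) -> RecoveryResult:
    """Estimate mu from transmission data by a log-linear least-squares fit.

    Fits ``ln(I/I0) = -mu x + c`` over the thickness series; the confidence
    interval comes from the t-distribution on the slope's standard error.
    Points with zero transmitted counts carry no usable information and are
    dropped with a warning.
    """
    x = np.asarray(thicknesses, dtype=float)
    I = np.asarray(transmitted, dtype=float)
    I0 = np.broadcast_to(np.asarray(incident, dtype=float), I.shape)
    keep = I > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} thickness point(s) with zero "
            "transmitted counts"
        )
        x, I, I0 = x[keep], I[keep], I0[keep]
    if x.size < 3:
        raise DomainError("need at least 3 usable thickness points")
    y = np.log(I / I0)
    fit = stats.linregress(x, y)
    mu = -fit.slope
    df = x.size - 2
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    half = tcrit * fit.stderr
    return RecoveryResult(
        mu=float(mu),
        ci_low=float(mu - half),
        ci_high=float(mu + half),
        stderr=float(fit.stderr),
        confidence=confidence,
        n_points=int(x.size),
    )


def run_recovery(exp: RecoveryExperiment, confidence: float = 0.99) -> RecoveryResult:
    """Simulate a transmission experiment and recover mu from it."""
    I = simulate_transmission_counts(exp)
    return mu_recovery(exp.thicknesses, I, exp.photons_per_thickness, confidence)
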