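"""Image-quality and energy-resolution statistics.

Works on 2-D projection maps of deposited energy (signal-to-noise ratio
over per-material footprint masks) and on per-event deposit lists (mean,
RMS, relative fluctuation, histograms).

SNR follows the radiographic definition mean / standard deviation over the
pixels of interest; the sample (n-1) standard deviation is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ProjectionMap",
    "SNRRow",
    "snr",
    "snr_report",
    "edep_stats",
    "combine_edep_stats",
    "fluctuation_metric",
    "export_histograms",
]


@dataclass
class ProjectionMap:
    """A 2-D deposited-energy image with per-volume footprint masks.

    ``pixels`` is the projected energy (keV) per pixel; ``masks`` maps a
    material name to a boolean footprint (pixels whose projected column
    intersects that material's volume).  Masks must be pairwise disjoint.
    """

    plane: str
    pixels: np.ndarray
    pixel_size: tuple[float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DomainError("projection map must be 2-D")
        if np.any(self.pixels < 0):
            raise DomainError("pixel values must be >= 0")
        cover = np.zeros(self.pixels.shape, dtype=int)
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.pixels.shape:
                raise DomainError(f"mask {name!r} does not match map shape")
            self.masks[name] = m
            cover += m
        if np.any(cover > 1):
            raise DomainError("footprint masks must be disjoint")

    def total(self) -> float:
        return float(self.pixels.sum())


@dataclass(frozen=True)
class SNRRow:
    label: str
    plane: str
    mean: float
    std: float
    snr: float
    infinite: bool = False


def snr(pmap: ProjectionMap, mask) -> SNRRow:
    """SNR = mean / sample std over the masked pixels of a projection map.

    *mask* is a mask name registered on the map, or a boolean array.
    A constant patch (std = 0) is reported with ``snr = inf`` and the
    ``infinite`` flag set.
    """
    if isinstance(mask, str):
        label = mask
        m = pmap.masks[mask]
    else:
        label = "custom"
        m = np.asarray(mask, dtype=bool)
    vals = pmap.pixels[m]
    if vals.size < 2:
        raise DomainError("mask must select at least 2 pixels")
    mean = float(vals.mean())
    std = float(vals.std(ddof=1))
    if std == 0.0:
        return SNRRow(label, pmap.plane, mean, 0.0, float("inf"), infinite=True)
    return SNRRow(label, pmap.plane, mean, std, mean / std)


def snr_report(maps: list[ProjectionMap]) -> pd.DataFrame:
    """SNR of every registered footprint on every map, as a tidy frame."""
    rows = []
    for pmap in maps:
        for name in pmap.masks:
            r = snr(pmap, name)
            rows.append(
                {
                    "material": r.label,
                    "plane": r.plane,
                    "mean": r.mean,
                    "std": r.std,
                    "snr": r.snr,
                    "infinite": r.infinite,
                }
            )
    return pd.DataFrame(rows)


def edep_stats(deposits) -> tuple[float, float]:
    """Mean and RMS deviation of per-event deposits (zero events included).

    RMS is the root of the mean squared deviation about the mean (population
    convention), matching how Monte Carlo histogram summaries report spread.
    """
    d = np.asarray(deposits, dtype=float)
    if d.size < 1:
        raise DomainError("need at least one event")
    mean = float(d.mean())
    rms = float(np.sqrt(np.mean((d - mean) ** 2)))
    return mean, rms


def combine_edep_stats(stats_a, stats_b) -> tuple[int, float, float]:
    """Pool two (n, mean, rms) summaries into the concatenated-set summary."""
    na, ma, ra = stats_a
    nb, mb, rb = stats_b
    n = na + nb
    mean = (na * ma + nb * mb) / n
    second = (na * (ra**2 + ma**2) + nb * (rb**2 + mb**2)) / n
    return n, mean, float(np.sqrt(max(second - mean**2, 0.0)))


@dataclass(frozen=True)
class FluctuationResult:
    percent: float
    scaled: float
    defined: bool = True


def fluctuation_metric(mean, rms, mean_initial_energy_kev) -> FluctuationResult:
    """Relative energy-deposit fluctuation.

    ``F = 100 * RMS / mean`` (percent) and ``F_scaled = F * sqrt(E0)`` with
    E0 the mean initial photon energy of the run; characterizes how noisy a
    material's energy response is.  Undefined (flagged) when mean == 0.
    """
    if mean == 0:
        return FluctuationResult(float("nan"), float("nan"), defined=False)
    if mean < 0:
        raise DomainError("mean deposit must be >= 0")
    f = 100.0 * rms / mean
    return FluctuationResult(f, f * np.sqrt(mean_initial_energy_kev))


def export_histograms(deposits, bins) -> pd.DataFrame:
    """Histogram per-event deposits; counts always sum to the event count."""
    d = np.asarray(deposits, dtype=float)
    counts, edges = np.histogram(d, bins=bins)
    # events falling outside the bin span are folded into the edge bins so
    # the count conservation invariant holds
    counts = counts.copy()
    counts[0] += int((d < edges[0]).sum())
    counts[-1] += int((d > edges[-1]).sum())
    return pd.DataFrame(
        {"bin_lo_keV": edges[:-1], "bin_hi_keV": edges[1:], "count": counts}
    )
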