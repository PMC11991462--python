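"""One-command reproduction of the radiopacity study.

``run_study`` executes the full chain — build the six study materials,
sweep the photon-interaction parameters over the diagnostic energy grid,
compute percent-increase tables against pure PEEK, run the Monte Carlo
imaging experiment, and derive per-material SNR — writing every table to a
manifest-tracked output directory.  Re-running with the same configuration
and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .attenuation import AttenuationCurve, compute_curve, percent_increase
from .errors import DomainError
from .materials import STUDY_MATERIAL_NAMES, Material, study_materials
from .metrics import ProjectionMap, snr_report
from .physics import EnergyGrid, interpolate_log_log
from .transport import BoxVolume, PlanarSource, SimulationTally, project, run_simulation

__all__ = [
    "StudyConfig",
    "StudyReport",
    "build_geometry",
    "projection_maps",
    "compare_materials",
    "run_study",
]

log = logging.getLogger("radiopeek")

DEFAULT_COMPARE_ENERGIES = (30.0, 50.0, 80.0, 100.0)
FULL_EVENTS = 1_000_000


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full study run."""

    materials: tuple = STUDY_MATERIAL_NAMES
    emin: float = 20.0
    emax: float = 120.0
    step: float = 0.1
    include_coherent: bool = True
    n_events: int = FULL_EVENTS
    seed: int = 20120
    source_width: float = 100.0
    source_height: float = 100.0
    source_z: float = -50.0
    box_half_widths: tuple = (2.5, 2.5, 2.5)
    box_gap: float = 2.0
    grid_shape: tuple = (100, 100, 100)
    outdir: str = "study_output"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kw = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        for key in ("materials", "box_half_widths", "grid_shape"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("outdir")
        d.pop("plots")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class StudyReport:
    config: StudyConfig
    outdir: Path
    manifest: dict
    curves: dict[str, AttenuationCurve]
    percent_increase: pd.DataFrame
    tally: SimulationTally
    snr: pd.DataFrame


def build_geometry(materials: list[Material], half_widths=(2.5, 2.5, 2.5), gap=2.0):
    """Boxes side by side along X with front faces at Z = 0."""
    hx, hy, hz = half_widths
    n = len(materials)
    pitch = 2 * hx + gap
    x0 = -(n - 1) * pitch / 2.0
    return [
        BoxVolume(mat, center=(x0 + i * pitch, 0.0, hz), half_widths=half_widths)
        for i, mat in enumerate(materials)
    ]


def _axis_centers(tally: SimulationTally, axis: int) -> np.ndarray:
    n = tally.grid.shape[axis]
    lo = tally.grid_lo[axis]
    return lo + (np.arange(n) + 0.5) * tally.voxel_size[axis]


def _footprint(centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (centers > lo - 1e-12) & (centers < hi + 1e-12)


def projection_maps(
    tally: SimulationTally, volumes: list[BoxVolume]
) -> list[ProjectionMap]:
    """Projection images with per-material footprint masks.

    XY and XZ are shared images with disjoint per-material masks (the boxes
    are separated along X).  In the YZ plane all boxes project onto the same
    footprint, so one restricted YZ map is built per material by projecting
    only that material's X-slab of the deposition grid.
    """
    xc, yc, zc = (_axis_centers(tally, a) for a in (0, 1, 2))
    vx, vy, vz = tally.voxel_size
    maps = []
    for plane, (ca, cb), psize in (
        ("XY", (xc, yc), (vx, vy)),
        ("XZ", (xc, zc), (vx, vz)),
    ):
        img = project(tally.grid, plane)
        masks = {}
        for box in volumes:
            fa = _footprint(ca, box.lo[0], box.hi[0])
            ax_b = 1 if plane == "XY" else 2
            fb = _footprint(cb, box.lo[ax_b], box.hi[ax_b])
            masks[box.material.name] = np.outer(fa, fb)
        maps.append(ProjectionMap(plane, img, psize, masks))
    for box in volumes:
        xsel = _footprint(xc, box.lo[0], box.hi[0])
        img = tally.grid[xsel].sum(axis=0)
        mask = np.outer(
            _footprint(yc, box.lo[1], box.hi[1]), _footprint(zc, box.lo[2], box.hi[2])
        )
        maps.append(
            ProjectionMap("YZ", img, (vy, vz), {box.material.name: mask})
        )
    return maps


def compare_materials(
    curves: dict[str, AttenuationCurve],
    baseline: str = "PEEK",
    energies=DEFAULT_COMPARE_ENERGIES,
) -> pd.DataFrame:
    """Percent increase of mu_m over the baseline material.

    One row per material: the increase at each sampling energy plus the
    min and max over the full common grid.  The baseline row is zero.
    """
    if baseline not in curves:
        raise DomainError(f"baseline {baseline!r} not among the curves")
    base = curves[baseline]
    rows = []
    for name, curve in curves.items():
        row = {"material": name}
        for e in energies:
            mu_c = interpolate_log_log(curve.grid.energies, curve.mu_m, e)
            mu_b = interpolate_log_log(base.grid.energies, base.mu_m, e)
            row[f"pct_{e:g}keV"] = percent_increase(mu_c, mu_b)
        full = percent_increase(curve.mu_m, base.mu_m)
        row["pct_grid_min"] = float(np.min(full))
        row["pct_grid_max"] = float(np.max(full))
        rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, files: list) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    files.append(str(path))


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all study stages and write the report to ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    log.info("stage 1/4: materials")
    try:
        all_mats = study_materials()
        mats = [all_mats[name] for name in config.materials]
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'materials' failed: {exc}") from exc

    log.info("stage 2/4: attenuation sweep %g-%g keV", config.emin, config.emax)
    try:
        grid = EnergyGrid.diagnostic(config.emin, config.emax, config.step)
        curves = {
            m.name: compute_curve(m, grid, config.include_coherent) for m in mats
        }
        for name, curve in curves.items():
            _write_csv(curve.to_frame(), out / "attenuation" / f"{name}.csv", files)
        pct = compare_materials(curves)
        _write_csv(pct, out / "percent_increase.csv", files)
    except Exception as exc:
        raise RuntimeError(f"stage 'attenuation' failed: {exc}") from exc

    log.info("stage 3/4: transport, %d events", config.n_events)
    try:
        volumes = build_geometry(mats, config.box_half_widths, config.box_gap)
        source = PlanarSource(
            width=config.source_width,
            height=config.source_height,
            z_position=config.source_z,
            emin=config.emin,
            emax=config.emax,
            n_events=config.n_events,
            seed=config.seed,
        )
        tally = run_simulation(
            source,
            volumes,
            grid_shape=tuple(config.grid_shape),
            include_coherent=config.include_coherent,
        )
        _write_csv(tally.summary_frame(), out / "tally_summary.csv", files)
        hists = []
        for i, name in enumerate(tally.volume_names):
            h = np.histogram(tally.per_event_deposits[:, i], bins=60,
                             range=(0.0, config.emax))
            hists.append(pd.DataFrame({
                "material": name,
                "bin_lo_keV": h[1][:-1],
                "bin_hi_keV": h[1][1:],
                "count": h[0],
            }))
        _write_csv(pd.concat(hists, ignore_index=True),
                   out / "edep_histograms.csv", files)
        gpath = out / "deposition_grid.h5"
        with h5py.File(gpath, "w") as fh:
            ds = fh.create_dataset("edep_keV", data=tally.grid, track_times=False)
            ds.attrs["grid_lo_cm"] = tally.grid_lo
            ds.attrs["grid_hi_cm"] = tally.grid_hi
        files.append(str(gpath))
    except Exception as exc:
        raise RuntimeError(f"stage 'transport' failed: {exc}") from exc

    log.info("stage 4/4: imaging metrics")
    try:
        maps = projection_maps(tally, volumes)
        snr = snr_report(maps)
        for plane in ("XY", "XZ", "YZ"):
            sub = snr[snr["plane"] == plane].drop(columns="plane")
            _write_csv(sub, out / f"snr_{plane.lower()}.csv", files)
        for pmap in maps:
            if pmap.plane == "YZ":
                name = next(iter(pmap.masks))
                path = out / "projections" / f"proj_yz_{name}.csv"
            else:
                path = out / "projections" / f"proj_{pmap.plane.lower()}.csv"
            _write_csv(pd.DataFrame(pmap.pixels), path, files)
        if config.plots:
            files += _make_plots(out, curves, maps)
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics' failed: {exc}") from exc

    manifest = {
        "package_version": _pkg_version,
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "scaled_down": config.n_events < FULL_EVENTS,
        "files": sorted(str(Path(f).relative_to(out)) for f in files),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return StudyReport(
        config=config,
        outdir=out,
        manifest=manifest,
        curves=curves,
        percent_increase=pct,
        tally=tally,
        snr=snr,
    )


def _make_plots(out: Path, curves, maps) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out / "plots"
    plot_dir.mkdir(exist_ok=True)
    written = []
    for attr, label, fname in (
        ("mu_m", "mass attenuation (cm$^2$/g)", "mu_m.png"),
        ("z_eff", "effective atomic number", "z_eff.png"),
        ("n_eff", "effective electron density (e/g)", "n_eff.png"),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, c in curves.items():
            ax.plot(c.grid.energies, getattr(c, attr), label=name, lw=1)
        ax.set_xlabel("photon energy (keV)")
        ax.set_ylabel(label)
        if attr == "mu_m":
            ax.set_yscale("log")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = plot_dir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    for pmap in maps:
        if pmap.plane == "YZ":
            continue
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.imshow(pmap.pixels.T, origin="lower", aspect="auto", cmap="inferno")
        ax.set_title(f"energy deposit map, {pmap.plane}")
        fig.tight_layout()
        p = plot_dir / f"map_{pmap.plane.lower()}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    return written
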