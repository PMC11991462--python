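"""Monte Carlo transport: sampling laws, interaction physics, geometry,
tallies, determinism and energy conservation."""

import numpy as np
import pytest
from scipy import stats

from radiopeek.attenuation import linear_mu, mixture_process_coeffs
from radiopeek.errors import DomainError, GeometryError
from radiopeek.materials import Composition, Material
from radiopeek.physics import ELECTRON_REST_KEV, kn_differential
from radiopeek.transport import (
    BoxVolume,
    PlanarSource,
    distance_to_interaction,
    do_compton,
    do_photoelectric,
    electron_range,
    project,
    run_simulation,
    sample_source,
    select_interaction,
)


class TestSource:
    def test_uniform_plate_and_energy(self, rng):
        src = PlanarSource(n_events=100_000, seed=5)
        pos, dirs, E = sample_source(src, rng)
        n = src.n_events
        sx = src.width / np.sqrt(12.0) / np.sqrt(n)
        assert abs(pos[:, 0].mean()) < 3 * sx
        assert abs(pos[:, 1].mean()) < 3 * sx
        se = (src.emax - src.emin) / np.sqrt(12.0) / np.sqrt(n)
        assert abs(E.mean() - 70.0) < 3 * se
        assert np.all(pos[:, 2] == src.z_position)

    def test_directions_are_plus_z(self, rng):
        _, dirs, _ = sample_source(PlanarSource(n_events=1000), rng)
        assert np.all(dirs == np.array([0.0, 0.0, 1.0]))

    def test_validation(self):
        with pytest.raises(DomainError):
            PlanarSource(width=-1)
        with pytest.raises(DomainError):
            PlanarSource(emin=60, emax=20)
        with pytest.raises(DomainError):
            PlanarSource(n_events=0)


class TestFreePath:
    def test_exponential_moments(self):
        mu = 0.7
        n = 1_000_000
        rng = np.random.default_rng(42)
        d = distance_to_interaction(mu, rng, n)
        assert abs(d.mean() - 1 / mu) < 3 * (1 / mu) / np.sqrt(n)
        # median is the HVL: half the draws exceed it
        frac = (d > np.log(2.0) / mu).mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_seeded_determinism(self):
        a = distance_to_interaction(1.0, np.random.default_rng(9), 1000)
        b = distance_to_interaction(1.0, np.random.default_rng(9), 1000)
        np.testing.assert_array_equal(a, b)

    def test_domain(self, rng):
        with pytest.raises(DomainError):
            distance_to_interaction(0.0, rng)


class TestInteractionSelection:
    def test_rayleigh_disabled_never_selected(self, mats, rng):
        picks = select_interaction(
            mats["PEEK"], np.full(5000, 60.0), rng, include_coherent=False
        )
        assert np.all(picks != 2)

    def test_photoelectric_fraction_matches_partials(self, mats):
        rng = np.random.default_rng(77)
        E = 25.0
        n = 100_000
        parts = mixture_process_coeffs(mats["PEEK-Bi2O3"], E)
        p = float(parts["pe"] / (parts["pe"] + parts["incoh"] + parts["coh"]))
        picks = select_interaction(mats["PEEK-Bi2O3"], np.full(n, E), rng)
        frac = (picks == 0).mean()
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_hydrogen_high_energy_is_compton(self):
        rng = np.random.default_rng(3)
        h = Material("H", Composition({"H": 1.0}), 0.09)
        picks = select_interaction(h, np.full(20_000, 120.0), rng)
        assert (picks == 1).mean() > 0.99


class TestCompton:
    def test_energy_conservation_and_bound(self):
        rng = np.random.default_rng(11)
        E = np.full(50_000, 60.0)
        cos_t, e_sc, e_el = do_compton(E, rng)
        np.testing.assert_allclose(e_sc + e_el, E, rtol=0, atol=1e-12)
        k = 60.0 / ELECTRON_REST_KEV
        assert np.all(e_sc >= 60.0 / (1 + 2 * k) - 1e-12)
        assert np.all(e_sc <= 60.0 + 1e-12)

    def test_angle_distribution_matches_klein_nishina(self):
        """Goodness of fit of sampled cos(theta) against the analytic density."""
        rng = np.random.default_rng(2024)
        n = 100_000
        E = np.full(n, 60.0)
        cos_t, _, _ = do_compton(E, rng)
        edges = np.linspace(-1.0, 1.0, 41)
        obs, _ = np.histogram(cos_t, bins=edges)
        # analytic bin probabilities by fine trapezoidal quadrature
        fine = np.linspace(-1.0, 1.0, 8001)
        dens = kn_differential(60.0, np.arccos(np.clip(fine, -1, 1)))
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                               * np.diff(fine))])
        cdf /= cdf[-1]
        pbin = np.diff(np.interp(edges, fine, cdf))
        chi2, p = stats.chisquare(obs, f_exp=n * pbin)
        assert p > 0.01

    def test_photoelectric_deposits_everything(self):
        assert do_photoelectric(88.5) == 88.5


class TestElectronRange:
    def test_zero_and_monotone(self, mats):
        peek = mats["PEEK"]
        assert electron_range(0.0, peek) == 0.0
        assert electron_range(100.0, peek) > electron_range(50.0, peek)

    def test_density_scaling(self, mats):
        r_peek = electron_range(80.0, mats["PEEK"])
        r_ta = electron_range(80.0, mats["PEEK-Ta"])
        assert r_peek / r_ta == pytest.approx(4.65 / 1.32, rel=1e-12)


def _slab(material, thickness=2.0, half_xy=2.0):
    return BoxVolume(
        material, center=(0.0, 0.0, thickness / 2.0),
        half_widths=(half_xy, half_xy, thickness / 2.0),
    )


class TestRunSimulation:
    def test_empty_geometry(self):
        src = PlanarSource(n_events=500, seed=1)
        tal = run_simulation(src, [])
        assert tal.total_deposited_kev() == 0.0
        assert tal.escaped_energy_kev == pytest.approx(tal.emitted_energy_kev)
        assert tal.grid.sum() == 0.0

    def test_overlap_rejected(self, mats):
        a = BoxVolume(mats["PEEK"], (0, 0, 2.5))
        b = BoxVolume(mats["bone"], (3.0, 0, 2.5))
        with pytest.raises(GeometryError):
            run_simulation(PlanarSource(n_events=10), [a, b])

    def test_beer_lambert_uncollided(self, mats):
        E0, x, n = 60.0, 2.0, 100_000
        mu = linear_mu(mats["PEEK-HA"], E0)
        src = PlanarSource(width=4, height=4, z_position=-5.0,
                           emin=E0, emax=E0, n_events=n, seed=8)
        tal = run_simulation(src, [_slab(mats["PEEK-HA"], x)], grid_shape=(8, 8, 8))
        p = np.exp(-mu * x)
        assert abs(tal.n_uncollided / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_energy_conservation(self, mats):
        src = PlanarSource(width=30, height=10, z_position=-10, n_events=20_000,
                           seed=13)
        vols = [
            BoxVolume(mats["PEEK"], (-6, 0, 2.5)),
            BoxVolume(mats["PEEK-Ta"], (0, 0, 2.5)),
            BoxVolume(mats["PEEK-BaSO4"], (6, 0, 2.5)),
        ]
        tal = run_simulation(src, vols, grid_shape=(30, 10, 10))
        balance = tal.total_deposited_kev() + tal.escaped_energy_kev
        assert balance == pytest.approx(tal.emitted_energy_kev, rel=1e-6)
        # voxel grid accounts for every deposit, per volume
        np.testing.assert_allclose(
            tal.grid_volume_sum(vols), tal.total_deposit_kev, rtol=1e-6
        )
        np.testing.assert_allclose(
            tal.per_event_deposits.sum(axis=0), tal.total_deposit_kev, rtol=1e-9
        )

    def test_seed_determinism_bitwise(self, mats):
        src = PlanarSource(width=6, height=6, z_position=-5, n_events=10_000, seed=21)
        vols = [_slab(mats["PEEK-BaSO4"])]
        a = run_simulation(src, vols, grid_shape=(10, 10, 10))
        b = run_simulation(src, vols, grid_shape=(10, 10, 10))
        np.testing.assert_array_equal(a.grid, b.grid)
        np.testing.assert_array_equal(a.per_event_deposits, b.per_event_deposits)
        assert a.escaped_energy_kev == b.escaped_energy_kev
        assert a.interaction_counts.tolist() == b.interaction_counts.tolist()


class TestProjection:
    def test_zero_grid(self):
        assert project(np.zeros((4, 5, 6)), "XY").sum() == 0.0

    def test_single_voxel_single_pixel(self):
        g = np.zeros((4, 5, 6))
        g[1, 2, 3] = 7.5
        for plane, shape in (("XY", (4, 5)), ("XZ", (4, 6)), ("YZ", (5, 6))):
            img = project(g, plane)
            assert img.shape == shape
            assert np.count_nonzero(img) == 1
            assert img.sum() == 7.5

    def test_sums_conserved_across_planes(self, rng):
        g = rng.random((6, 7, 8))
        s = {p: project(g, p).sum() for p in ("XY", "XZ", "YZ")}
        assert s["XY"] == pytest.approx(s["XZ"]) == pytest.approx(s["YZ"])
        assert s["XY"] == pytest.approx(g.sum())

    def test_unknown_plane(self):
        with pytest.raises(DomainError):
            project(np.zeros((2, 2, 2)), "QQ")
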