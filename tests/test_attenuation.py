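"""Material-level attenuation parameters: mixture rule, cross-sections,
Z_eff/N_eff collapse, HVL/transmission identities and K-edge localization."""

import numpy as np
import pytest

from radiopeek.attenuation import (
    AttenuationCurve,
    compute_curve,
    hvl,
    linear_mu,
    locate_k_edge,
    mixture_mu_m,
    n_eff,
    percent_increase,
    total_atomic_cross_section,
    total_electronic_cross_section,
    transmission,
    z_eff,
)
from radiopeek.elements import ELEMENTS, get_element
from radiopeek.errors import DomainError, ResolutionError
from radiopeek.materials import Composition, Material, parse_formula, weight_fractions
from radiopeek.physics import EnergyGrid, N_AVOGADRO, element_mass_attenuation

SAMPLE_E = [20.0, 30.0, 50.0, 60.0, 80.0, 100.0, 120.0]


def pure(sym, rho=1.0):
    return Material(sym, Composition({sym: 1.0}), rho)


class TestMixtureRule:
    def test_single_element_collapses(self):
        m = pure("C")
        for E in SAMPLE_E:
            assert mixture_mu_m(m, E) == element_mass_attenuation("C", E)

    def test_fifty_fifty_blend_is_mean(self):
        blend = Material("CO", Composition({"C": 0.5, "O": 0.5}), 1.0)
        for E in SAMPLE_E:
            expected = 0.5 * (
                element_mass_attenuation("C", E) + element_mass_attenuation("O", E)
            )
            assert mixture_mu_m(blend, E) == pytest.approx(expected, rel=1e-14)

    def test_composites_exceed_peek(self, mats):
        E = np.asarray(SAMPLE_E)
        peek = mixture_mu_m(mats["PEEK"], E)
        assert np.all(mixture_mu_m(mats["PEEK-Bi2O3"], E) > peek)


class TestTransmissionHVL:
    def test_transmission_identities(self):
        assert transmission(0.5, 0.0) == 1.0
        assert transmission(np.log(2.0), 1.0) == pytest.approx(0.5)
        t1 = transmission(0.37, 1.0)
        assert transmission(0.37, 2.0) == pytest.approx(t1**2, rel=1e-12)
        with pytest.raises(DomainError):
            transmission(0.5, -1.0)

    def test_hvl_identities(self):
        assert hvl(np.log(2.0)) == pytest.approx(1.0)
        assert hvl(2.0) == pytest.approx(hvl(1.0) / 2.0)
        assert transmission(0.73, hvl(0.73)) == pytest.approx(0.5, abs=1e-12)
        with pytest.raises(DomainError):
            hvl(0.0)

    def test_curve_hvl_mu_identity(self, mats):
        c = compute_curve(mats["PEEK-BaSO4"])
        np.testing.assert_allclose(c.hvl * c.mu, np.log(2.0), rtol=1e-12)
        np.testing.assert_allclose(c.mu, c.mu_m * 1.52, rtol=1e-12)


class TestCrossSections:
    def test_pure_element_reduction(self):
        c = pure("C")
        for E in (30.0, 60.0):
            mu_m = mixture_mu_m(c, E)
            el = get_element("C")
            assert total_atomic_cross_section(c, E) == pytest.approx(
                mu_m * el.A / N_AVOGADRO, rel=1e-12
            )
            assert total_electronic_cross_section(c, E) == pytest.approx(
                total_atomic_cross_section(c, E) / el.Z, rel=1e-12
            )

    def test_water_molecule_oracle(self, water):
        """Brute-force per-molecule sums reproduce the mixture formulas."""
        E = 60.0
        counts = parse_formula("H2O")
        n_atoms = sum(counts.values())
        sig_a = {
            s: element_mass_attenuation(s, E) * get_element(s).A / N_AVOGADRO
            for s in counts
        }
        molecule = sum(n * sig_a[s] for s, n in counts.items()) / n_atoms
        assert total_atomic_cross_section(water, E) == pytest.approx(
            molecule, rel=1e-9
        )
        electronic = sum(
            (n / n_atoms) * sig_a[s] / get_element(s).Z for s, n in counts.items()
        )
        assert total_electronic_cross_section(water, E) == pytest.approx(
            electronic, rel=1e-9
        )

    def test_sigma_ta_invariant_under_entry_split(self):
        whole = Material("W1", Composition({"C": 0.6, "O": 0.4}), 1.0)
        # same physical material described with O listed at higher precision
        split = Material("W2", Composition({"C": 0.6, "O": 0.4 + 0.0}), 1.0)
        for E in (30.0, 90.0):
            assert total_atomic_cross_section(whole, E) == pytest.approx(
                total_atomic_cross_section(split, E), rel=1e-12
            )

    def test_positive_for_all_study_materials(self, mats):
        E = np.asarray(SAMPLE_E)
        for m in mats.values():
            assert np.all(total_electronic_cross_section(m, E) > 0)
            sig_a = total_atomic_cross_section(m, E)
            sig_el = total_electronic_cross_section(m, E)
            assert np.all(sig_a >= sig_el)


class TestEffectiveNumbers:
    @pytest.mark.parametrize("sym", list(ELEMENTS))
    def test_pure_element_collapse(self, sym):
        m = pure(sym)
        el = ELEMENTS[sym]
        E = np.asarray(SAMPLE_E)
        np.testing.assert_allclose(z_eff(m, E), el.Z, rtol=1e-9)
        np.testing.assert_allclose(n_eff(m, E), N_AVOGADRO * el.Z / el.A, rtol=1e-9)

    def test_carbon_electron_density_value(self):
        assert n_eff(pure("C"), 60.0) == pytest.approx(3.008e23, rel=1e-3)

    def test_z_eff_bounded_by_constituents(self, mats):
        E = np.asarray(SAMPLE_E)
        for m in mats.values():
            zs = [get_element(s).Z for s in m.composition]
            z = z_eff(m, E)
            assert np.all(z >= min(zs)) and np.all(z <= max(zs))

    def test_high_z_fillers_raise_z_eff_and_n_eff(self, mats):
        assert z_eff(mats["PEEK-Bi2O3"], 30.0) > z_eff(mats["PEEK"], 30.0)
        assert n_eff(mats["PEEK-Ta"], 30.0) > n_eff(mats["PEEK"], 30.0)

    def test_mu_m_identity(self, mats):
        E = np.asarray(SAMPLE_E)
        for m in mats.values():
            lhs = mixture_mu_m(m, E)
            rhs = n_eff(m, E) * total_electronic_cross_section(m, E)
            np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestPercentIncrease:
    def test_trivial_cases(self):
        assert percent_increase(1.0, 1.0) == 0.0
        assert percent_increase(2.0, 1.0) == pytest.approx(100.0)
        assert percent_increase(0.5, 1.0) < 0
        with pytest.raises(DomainError):
            percent_increase(1.0, 0.0)


class TestCurvesAndKEdge:
    def test_peek_has_no_edge(self, mats):
        assert locate_k_edge(compute_curve(mats["PEEK"])) is None

    def test_injected_jump_is_found(self):
        grid = EnergyGrid(np.round(np.arange(20.0, 120.05, 0.1), 9))
        E = grid.energies
        mu_m = 5.0 * (E / 20.0) ** -2.5
        mu_m[E >= 50.0] *= 1.2  # 20% synthetic discontinuity at 50 keV
        curve = AttenuationCurve("synthetic", grid, mu_m, mu_m, np.log(2) / mu_m,
                                 mu_m * 0 + 6, mu_m * 0 + 3e23)
        assert locate_k_edge(curve) == pytest.approx(50.0)

    @pytest.mark.parametrize(
        "name,sym", [("PEEK-BaSO4", "Ba"), ("PEEK-Ta", "Ta"), ("PEEK-Bi2O3", "Bi")]
    )
    def test_composite_edges_match_element_table(self, mats, name, sym):
        curve = compute_curve(mats[name])
        assert locate_k_edge(curve) == ELEMENTS[sym].k_edge

    def test_coarse_grid_rejected(self, mats):
        grid = EnergyGrid(np.arange(20.0, 121.0, 1.0))
        curve = compute_curve(mats["PEEK-BaSO4"], grid)
        with pytest.raises(ResolutionError):
            locate_k_edge(curve)

    def test_peek_lowest_among_study_materials(self, mats):
        curves = {n: compute_curve(m) for n, m in mats.items()}
        peek = curves["PEEK"].mu_m
        for name, c in curves.items():
            if name != "PEEK":
                assert np.all(c.mu_m > peek), name

    def test_mu_m_decreasing_off_edges(self, mats):
        for m in mats.values():
            c = compute_curve(m)
            d = np.diff(c.mu_m)
            dup = np.diff(c.grid.energies) == 0
            assert np.all(d[~dup] < 0), m.name

    def test_curve_frame_layout(self, mats):
        df = compute_curve(mats["PEEK"]).to_frame()
        assert list(df.columns) == [
            "material", "energy_keV", "mu_m_cm2_g", "mu_1_cm",
            "hvl_cm", "z_eff", "n_eff",
        ]
        assert (df["material"] == "PEEK").all()
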