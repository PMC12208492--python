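"""Closed-form electrodiffusion: Nernst potentials, intramembrane profiles,
harmonic means, the conductance-permeability link and the GHK current."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnpneuro.core_gnp import (
    IonSpecies,
    MembraneGeometry,
    charge_sensitivity_mV_per_mM,
    conductance_per_area,
    ghk_current_density,
    ghk_flux_current_density,
    harmonic_mean_concentration,
    intramembrane_profile,
    nernst_potential,
    voltage_from_charge,
)

from conftest import quad_harmonic_mean


class TestNernst:
    def test_symmetric_solution_is_zero(self, constants):
        ion = IonSpecies("X", 1, 50.0, 50.0)
        assert nernst_potential(ion, constants) == 0.0

    @pytest.mark.parametrize(
        "name,z,ci,co,expected",
        [("Cl", -1, 10.41, 134.59, -68.18), ("K", 1, 96.83, 3.17, -91.08)],
    )
    def test_physiological_reversals(self, constants, name, z, ci, co, expected):
        ion = IonSpecies(name, z, ci, co)
        assert nernst_potential(ion, constants) == pytest.approx(expected, abs=0.01)

    def test_zero_concentration_rejected(self, constants):
        with pytest.raises(ValueError):
            nernst_potential(IonSpecies("X", 1, 0.0, 10.0), constants)


class TestProfile:
    def test_boundaries_exact(self, phys_ions, constants):
        k = phys_ions["K"]
        assert intramembrane_profile(k, -68.17, 0.0, constants) == k.c_out
        assert intramembrane_profile(k, -68.17, 1.0, constants) == k.c_in

    def test_zero_field_is_linear(self, phys_ions, constants):
        na = phys_ions["Na"]
        for xi in (0.25, 0.5, 0.75):
            expected = na.c_out + xi * (na.c_in - na.c_out)
            assert intramembrane_profile(na, 0.0, xi, constants) == pytest.approx(expected, rel=1e-12)

    @given(v=st.floats(-150, 150), xi=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_profile_positive_for_positive_baths(self, v, xi):
        ion = IonSpecies("K", 1, 96.83, 3.17)
        assert intramembrane_profile(ion, v, xi) > 0.0


class TestHarmonicMean:
    def test_symmetric_baths_give_bath_value(self, constants):
        ion = IonSpecies("X", 1, 42.0, 42.0)
        for v in (-80.0, 0.0, 33.0):
            assert harmonic_mean_concentration(ion, v, constants) == 42.0

    def test_known_values_at_rest(self, phys_ions, constants):
        k = harmonic_mean_concentration(phys_ions["K"], -68.17, constants)
        assert k == pytest.approx(13.9, abs=0.1)
        ecl = nernst_potential(phys_ions["Cl"], constants)
        cl = harmonic_mean_concentration(phys_ions["Cl"], ecl, constants)
        assert cl == pytest.approx(28.9, abs=0.1)

    @pytest.mark.parametrize("name", ["K", "Na", "Cl"])
    def test_matches_quadrature_oracle_on_grid(self, phys_ions, constants, name):
        """Closed form vs direct quadrature of the profile, including the
        removable singularities at V = 0 and V = E_q."""
        ion = phys_ions[name]
        eq = nernst_potential(ion, constants)
        grid = np.concatenate([np.linspace(-120, 120, 46), [0.0, eq, eq + 1e-7, 1e-9]])
        for v in grid:
            closed = harmonic_mean_concentration(ion, v, constants)
            oracle = quad_harmonic_mean(ion, v, constants)
            assert closed == pytest.approx(oracle, rel=1e-6), f"V={v}"

    def test_continuity_through_singular_points(self, phys_ions, constants):
        cl = phys_ions["Cl"]
        ecl = nernst_potential(cl, constants)
        for v0 in (0.0, ecl):
            vals = [harmonic_mean_concentration(cl, v0 + d, constants) for d in (-1e-5, -1e-7, 0.0, 1e-7, 1e-5)]
            assert max(vals) - min(vals) < 1e-6 * vals[2]

    def test_monotonicity_directions(self, phys_ions, constants):
        """Efflux-gradient cations rise with V (outward rectification),
        influx-gradient cations fall; anions mirror under z -> -z with
        swapped baths."""
        vs = np.linspace(-100, 100, 41)
        k = [harmonic_mean_concentration(phys_ions["K"], v, constants) for v in vs]
        na = [harmonic_mean_concentration(phys_ions["Na"], v, constants) for v in vs]
        assert np.all(np.diff(k) > 0)  # c_in > c_out, z=+1: increasing
        assert np.all(np.diff(na) < 0)  # c_out > c_in, z=+1: decreasing
        mirrored = IonSpecies("Km", -1, phys_ions["K"].c_out, phys_ions["K"].c_in)
        m = [harmonic_mean_concentration(mirrored, v, constants) for v in vs]
        assert np.allclose(m, k, rtol=1e-12)

    def test_both_zero_rejected(self, constants):
        with pytest.raises(ValueError):
            harmonic_mean_concentration(IonSpecies("X", 1, 0.0, 0.0), constants)


class TestConductanceAndCurrent:
    @pytest.mark.parametrize(
        "P,name,expected,tol",
        [(2.00e-8, "K", 0.10, 0.005), (4.00e-9, "Cl", 0.042, 0.0005)],
    )
    def test_leak_conductances_reproduce_linearized_constants(self, phys_ions, constants, P, name, expected, tol):
        g = conductance_per_area(P, phys_ions[name], -68.17, constants)
        assert g == pytest.approx(expected, abs=tol)

    def test_symmetric_baths_conductance_v_independent(self, constants):
        ion = IonSpecies("X", 1, 30.0, 30.0)
        gs = [conductance_per_area(1e-8, ion, v, constants) for v in (-90, -30, 0, 60)]
        assert max(gs) - min(gs) < 1e-15
        expected = constants.F ** 2 * 1e-8 * 30.0 / constants.RT * 0.1
        assert gs[0] == pytest.approx(expected, rel=1e-12)

    def test_current_vanishes_at_reversal(self, phys_ions, constants):
        for ion in phys_ions.values():
            eq = nernst_potential(ion, constants)
            assert abs(ghk_current_density(1e-8, ion, eq, constants)) < 1e-9

    def test_small_voltage_limit_is_diffusive_flux(self, phys_ions, constants):
        na = phys_ions["Na"]
        expected = na.z * constants.F * 1e-8 * (na.c_in - na.c_out) * 100.0  # uA/cm^2
        assert ghk_flux_current_density(1e-8, na, 0.0, constants) == pytest.approx(expected, rel=1e-9)

    def test_ohmic_identity_everywhere(self, phys_ions, constants):
        """I = -G (V - E_q) holds to 1e-9 relative on a grid including the
        singular points: the GHK current IS the GNP conductance times the
        driving force."""
        for ion in phys_ions.values():
            eq = nernst_potential(ion, constants)
            for v in np.concatenate([np.linspace(-110, 110, 45), [0.0, eq]]):
                lhs = ghk_current_density(1e-8, ion, v, constants)
                g = conductance_per_area(1e-8, ion, v, constants)
                rhs = -g * (v - eq)  # mS/cm^2 * mV == uA/cm^2
                scale = max(abs(lhs), abs(rhs), 1e-6)
                assert abs(lhs - rhs) / scale < 1e-9, f"{ion.name} V={v}"

    def test_rest_leak_potassium_balances_twice_pump(self, phys_ions, constants):
        """At the resting balance the leak K current magnitude is ~2 x 1.16
        uA/cm^2 (the pump's 2-for-3 stoichiometry with negligible gated K)."""
        i = ghk_current_density(2.00e-8, phys_ions["K"], -68.17, constants)
        assert i == pytest.approx(-2 * 1.16, abs=0.05)

    def test_linear_iv_limit_as_gradient_vanishes(self, constants):
        """As the gradient shrinks at fixed total, the I-V curve approaches
        a straight line."""
        vs = np.linspace(-80, 80, 33)
        total = 100.0
        last = np.inf
        for delta in (40.0, 4.0, 0.4, 1e-4):
            ion = IonSpecies("X", 1, (total + delta) / 2, (total - delta) / 2)
            i = np.array([ghk_current_density(1e-8, ion, v, constants) for v in vs])
            coef = np.polyfit(vs, i, 1)
            dev = np.max(np.abs(i - np.polyval(coef, vs))) / np.max(np.abs(i))
            assert dev < last
            last = dev
        assert last < 1e-6


class TestVoltageFromCharge:
    def test_exact_neutrality_gives_zero(self, constants):
        geom = MembraneGeometry()
        ions = [
            IonSpecies("K", 1, 96.83, 3.17),
            IonSpecies("Na", 1, 23.58, 131.42),
            IonSpecies("Cl", -1, 10.41, 134.59),
        ]
        # this particular set balances [A-]_i = 110 exactly
        assert voltage_from_charge(ions, geom, constants) == pytest.approx(0.0, abs=1e-9)

    def test_sensitivity_coefficient(self, constants):
        assert charge_sensitivity_mV_per_mM(MembraneGeometry(), constants) == pytest.approx(1.21e4, rel=0.005)

    def test_resting_potential_needs_micromolar_imbalance(self, constants):
        """-68.17 mV corresponds to a net-charge offset of a few uM."""
        offset_mM = -68.17 / charge_sensitivity_mV_per_mM(MembraneGeometry(), constants)
        assert 1e-3 < abs(offset_mM) < 1e-2

    def test_linearity_in_each_concentration(self, constants):
        geom = MembraneGeometry()
        base = [IonSpecies("K", 1, 96.83, 3.17)]
        v0 = voltage_from_charge(base, geom, constants)
        v1 = voltage_from_charge([IonSpecies("K", 1, 97.83, 3.17)], geom, constants)
        v2 = voltage_from_charge([IonSpecies("K", 1, 98.83, 3.17)], geom, constants)
        assert v1 - v0 == pytest.approx(v2 - v1, rel=1e-9)
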