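"""Channel characterization: linearity condition, permeability calibration,
per-ion decomposition, apparent vs latent conductance and reversal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gnpneuro.channels import (
    ChannelSpec,
    ampa_channel,
    ampa_glur2less_channel,
    apparent_conductance_reversal,
    gabaa_channel,
    latent_conductance_reversal,
    leak_channel,
    linearity_ratio,
    membrane_average_permeability,
    per_ion_conductance,
    permeabilities_from_linear_conductance,
    pore_cross_section,
    single_channel_current,
    single_channel_iv,
)
from gnpneuro.core_gnp import IonSpecies, harmonic_mean_concentration, nernst_potential


class TestLinearityCondition:
    def test_ampa_na_over_k_ratio(self, phys_ions):
        assert linearity_ratio(phys_ions["K"], phys_ions["Na"]) == pytest.approx(0.87, abs=0.005)

    def test_gabaa_chloride_excess(self):
        """With the HCO3 gradient at 15/25 mM and ratio 0.2, exact linearity
        needs [Cl]i 2 mM above [Cl]o: solving the condition for the chloride
        gradient gives +2 mM."""
        hco3 = IonSpecies("HCO3", -1, 15.0, 25.0)
        # ratio = 0.2 = -(Cl_i - Cl_o)/(HCO3_i - HCO3_o) => Cl_i - Cl_o = +2
        gradient = -0.2 * (hco3.c_in - hco3.c_out)
        assert gradient == pytest.approx(2.0)

    def test_gradient_free_reference_ion(self):
        a = IonSpecies("A", 1, 10.0, 10.0)
        b = IonSpecies("B", 1, 5.0, 15.0)
        assert linearity_ratio(a, b) == 0.0

    def test_gradient_free_compensator_rejected(self):
        a = IonSpecies("A", 1, 5.0, 15.0)
        b = IonSpecies("B", 1, 10.0, 10.0)
        with pytest.raises(ZeroDivisionError):
            linearity_ratio(a, b)


class TestCalibration:
    def test_gabaa_permeabilities(self, constants):
        spec = gabaa_channel(constants)
        P = dict((ion.name, p) for ion, p in spec.permeants)
        assert P["Cl"] == pytest.approx(7.04e-2, rel=5e-3)
        assert P["HCO3"] == pytest.approx(1.41e-2, rel=5e-3)
        assert P["HCO3"] / P["Cl"] == pytest.approx(0.2, rel=1e-12)

    def test_ampa_permeabilities(self, constants):
        spec = ampa_channel(constants)
        P = dict((ion.name, p) for ion, p in spec.permeants)
        assert P["K"] == pytest.approx(8.99e-2, rel=5e-3)
        assert P["Na"] == pytest.approx(7.80e-2, rel=5e-3)

    @given(
        p1=st.floats(1e-3, 1.0),
        ratio=st.floats(0.05, 2.0),
        c2i=st.floats(5.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovery(self, constants, p1, ratio, c2i):
        """Permeability -> linear slope -> permeability is the identity on
        baths satisfying the linearity condition."""
        c2o = c2i + 10.0
        ion2 = IonSpecies("B", 1, c2i, c2o)
        p2 = p1 * ratio
        # place the ion1 gradient exactly at the linearity condition
        grad = -(p2 / p1) * (c2i - c2o)
        ion1 = IonSpecies("A", 1, 50.0 + grad / 2, 50.0 - grad / 2)
        if abs(ion1.c_out * ion2.c_in - ion2.c_out * ion1.c_in) < 1e-6:
            return  # degenerate determinant; calibration undefined
        spec = ChannelSpec("rt", ((ion1, p1), (ion2, p2)), pore_cross_section(5e-10))
        # forward: measure the (constant) slope of the total I-V
        vs = np.array([-60.0, 60.0])
        i = [single_channel_current(spec, v, constants)[1] for v in vs]
        slope_pS = -(i[1] - i[0]) / (vs[1] - vs[0]) * 1e3  # pA/mV -> nS? pA/mV = nS = 1000 pS
        q1, q2 = permeabilities_from_linear_conductance(slope_pS, spec, constants)
        assert q1 == pytest.approx(p1, rel=1e-8)
        assert q2 == pytest.approx(p2, rel=1e-8)


class TestPerIonConductance:
    def test_ratio_is_weighted_by_harmonic_means(self, constants):
        spec = gabaa_channel(constants)
        (cl, Pcl), (hco3, Phco3) = spec.permeants
        for v in (-80.0, -20.0, 40.0):
            g_cl = per_ion_conductance(spec, 0, v, constants)
            g_h = per_ion_conductance(spec, 1, v, constants)
            expected = (Pcl / Phco3) * (
                harmonic_mean_concentration(cl, v, constants)
                / harmonic_mean_concentration(hco3, v, constants)
            )
            assert g_cl / g_h == pytest.approx(expected, rel=1e-12)

    def test_ratio_not_constant_when_gradients_differ(self, constants):
        spec = gabaa_channel(constants)
        ratios = [
            per_ion_conductance(spec, 0, v, constants) / per_ion_conductance(spec, 1, v, constants)
            for v in (-80.0, 0.0, 80.0)
        ]
        assert max(ratios) - min(ratios) > 1e-3

    def test_symmetric_baths_ratio_v_independent(self, constants):
        a = IonSpecies("A", 1, 20.0, 20.0)
        b = IonSpecies("B", 1, 50.0, 50.0)
        spec = ChannelSpec("sym", ((a, 0.3), (b, 0.1)), 1e-18)
        ratios = [
            per_ion_conductance(spec, 0, v, constants) / per_ion_conductance(spec, 1, v, constants)
            for v in (-70.0, 0.0, 70.0)
        ]
        assert max(ratios) - min(ratios) < 1e-12
        assert ratios[0] == pytest.approx((0.3 * 20) / (0.1 * 50), rel=1e-12)


class TestApparentLatent:
    def test_gabaa_apparent_reversal(self, constants):
        spec = gabaa_channel(constants)
        _, ec_a = apparent_conductance_reversal(spec, -60.0, constants)
        assert ec_a == pytest.approx(-62.34, abs=0.1)

    def test_apparent_reversal_voltage_independent(self, constants):
        spec = gabaa_channel(constants)
        revs = {apparent_conductance_reversal(spec, v, constants)[1] for v in (-90.0, 0.0, 55.0)}
        assert max(revs) - min(revs) < 1e-12

    def test_reference_permeant_choice_is_irrelevant(self, constants):
        spec = gabaa_channel(constants)
        for v in (-75.0, 12.0):
            a = apparent_conductance_reversal(spec, v, constants, reference_index=0)
            b = apparent_conductance_reversal(spec, v, constants, reference_index=1)
            assert a[0] == pytest.approx(b[0], rel=1e-12)
            assert a[1] == pytest.approx(b[1], rel=1e-12)

    def test_single_permeant_reduces_to_nernst(self, constants):
        ion = IonSpecies("K", 1, 96.83, 3.17)
        spec = ChannelSpec("k-only", ((ion, 0.25),), 1e-18)
        _, ec_a = apparent_conductance_reversal(spec, -50.0, constants)
        assert ec_a == pytest.approx(nernst_potential(ion, constants), rel=1e-12)

    def test_mixed_valence_has_no_apparent_form(self, constants):
        with pytest.raises(ValueError):
            apparent_conductance_reversal(ampa_glur2less_channel(constants), 0.0, constants)

    @pytest.mark.parametrize("maker", [gabaa_channel, ampa_channel])
    def test_both_forms_reproduce_total_current(self, constants, maker):
        """-g (V - E) in either decomposition equals the summed per-ion GHK
        currents at every grid voltage (<1e-9 relative)."""
        spec = maker(constants)
        for v in np.linspace(-90, 90, 19):
            _, total = single_channel_current(spec, v, constants)
            gc_a, ec_a = apparent_conductance_reversal(spec, v, constants)
            gc_l, ec_l = latent_conductance_reversal(spec, v, constants)
            for g, e in ((gc_a, ec_a), (gc_l, ec_l)):
                recon = -g * (v - e) * 1e-3  # pS * mV = 1e-3 pA
                scale = max(abs(total), 1e-6)  # floor in pA, for the zero crossing
                assert abs(recon - total) / scale < 1e-9

    def test_latent_reproduces_mixed_valence_channel(self, constants):
        spec = ampa_glur2less_channel(constants)
        for v in (-80.0, 0.0, 80.0):
            _, total = single_channel_current(spec, v, constants)
            gc_l, ec_l = latent_conductance_reversal(spec, v, constants)
            assert -gc_l * (v - ec_l) * 1e-3 == pytest.approx(total, rel=1e-9, abs=1e-12)

    def test_latent_pair_voltage_dependent_even_for_linear_channel(self, constants):
        spec = ampa_channel(constants)
        gs = [latent_conductance_reversal(spec, v, constants) for v in (-80.0, 0.0, 80.0)]
        assert max(g for g, _ in gs) - min(g for g, _ in gs) > 0.1  # pS
        assert max(e for _, e in gs) - min(e for _, e in gs) > 0.1  # mV


class TestSingleChannelIV:
    def test_calibrated_ampa_is_linear_with_30pS_slope(self, constants):
        spec = ampa_channel(constants)
        vs = np.linspace(-80, 80, 33)
        iv = single_channel_iv(spec, vs, constants)
        tot = iv["I_total_pA"].to_numpy()
        coef = np.polyfit(vs, tot, 1)
        assert -coef[0] * 1e3 == pytest.approx(30.0, rel=1e-6)
        dev = np.max(np.abs(tot - np.polyval(coef, vs))) / np.max(np.abs(tot))
        assert dev < 1e-6

    def test_gabaa_outward_rectification(self, constants):
        """|I| above the reversal exceeds |I| symmetrically below it: the
        physiological chloride gradient makes the GABAA I-V outward."""
        spec = gabaa_channel(constants)
        _, ec_a = apparent_conductance_reversal(spec, 0.0, constants)
        _, i_up = single_channel_current(spec, ec_a + 60.0, constants)
        _, i_dn = single_channel_current(spec, ec_a - 60.0, constants)
        assert abs(i_up) > abs(i_dn)

    def test_calcium_component_turns_ampa_inward(self, constants):
        spec = ampa_glur2less_channel(constants)
        _, ec_l = latent_conductance_reversal(spec, 0.0, constants)
        zero = ec_l  # use the latent reversal near the actual zero crossing
        _, i_up = single_channel_current(spec, zero + 60.0, constants)
        _, i_dn = single_channel_current(spec, zero - 60.0, constants)
        assert abs(i_dn) > abs(i_up)

    def test_leak_channel_outward(self, constants):
        spec = leak_channel()
        gc_l, ec_l = latent_conductance_reversal(spec, 0.0, constants)
        _, i_up = single_channel_current(spec, ec_l + 60.0, constants)
        _, i_dn = single_channel_current(spec, ec_l - 60.0, constants)
        assert abs(i_up) > abs(i_dn)

    def test_iv_table_totals_and_columns(self, constants):
        iv = single_channel_iv(gabaa_channel(constants), [-40.0, 0.0], constants)
        assert list(iv["V_mV"]) == [-40.0, 0.0]
        np.testing.assert_allclose(
            iv["I_Cl_pA"] + iv["I_HCO3_pA"], iv["I_total_pA"], rtol=1e-12
        )


class TestMembraneAveraging:
    def test_zero_density_and_linearity(self):
        sc = pore_cross_section(5e-10)
        assert membrane_average_permeability(0.1, 0.0, sc) == 0.0
        one = membrane_average_permeability(0.1, 1e7, sc)
        two = membrane_average_permeability(0.1, 2e7, sc)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_reproduces_canonical_averaged_permeabilities(self, constants):
        """The stated densities with the calibrated single-channel
        permeabilities reproduce the canonical leak and glutamate averaged
        permeabilities."""
        sc = pore_cross_section(5e-10)
        assert membrane_average_permeability(2.55e-1, 1e7, sc) == pytest.approx(2.00e-8, rel=0.01)
        assert membrane_average_permeability(5.08e-2, 1e7, sc) == pytest.approx(4.00e-9, rel=0.01)
        ampa = ampa_channel(constants)
        pk = dict((i.name, p) for i, p in ampa.permeants)["K"]
        assert membrane_average_permeability(pk, 4e6, sc) == pytest.approx(2.82e-9, rel=0.01)

    def test_open_probability_bounds(self):
        with pytest.raises(ValueError):
            membrane_average_permeability(0.1, 1e7, 1e-18, open_probability=1.2)
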