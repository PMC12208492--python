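"""Closed-form transmembrane electrodiffusion.

The Gauss-Nernst-Planck (GNP) picture treats the membrane as a slab
(extracellular face at relative depth xi = 0, intracellular at xi = 1) in
which the electric field is uniform by Gauss's law, so the steady-state
intramembrane concentration profile is the classical constant-field
(Goldman) profile.  Its harmonic mean c̄ is what converts a permeability
into a conductance density:

    G_q = z^2 F^2 P_q c̄_q / (R T)

and the resulting ohmic-looking current G_q (V - E_q) is *identically* the
GHK current, which is how this module bridges conductance-based and
permeability-based models.

All the removable singularities of the closed forms (V = 0 and V = E_q)
are handled with expm1-style formulations plus short series expansions, so
every function here is continuous in V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import (
    A_PER_M2_TO_UA_PER_CM2,
    DEFAULT_CONSTANTS,
    S_PER_M2_TO_MS_PER_CM2,
    UF_PER_CM2_TO_F_PER_M2,
    PhysicalConstants,
)

__all__ = [
    "IonSpecies",
    "MembraneGeometry",
    "nernst_potential",
    "intramembrane_profile",
    "harmonic_mean_concentration",
    "conductance_per_area",
    "ghk_current_density",
    "ghk_flux_current_density",
    "voltage_from_charge",
    "charge_sensitivity_mV_per_mM",
]

_SIGMA_TOL = 1e-9


@dataclass(frozen=True)
class IonSpecies:
    """An ion with its transmembrane concentrations.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"K"``.
    z : int
        Valence (nonzero integer).
    c_in, c_out : float
        Intra-/extracellular concentration in mM (nonnegative).
    sigma : float, optional
        Conservation constant c_in + c_out for closed two-compartment
        systems.  When given it must match c_in + c_out.
    """

    name: str
    z: int
    c_in: float
    c_out: float
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"{self.name}: valence must be nonzero")
        if self.c_in < 0 or self.c_out < 0:
            raise ValueError(f"{self.name}: concentrations must be nonnegative")
        if self.sigma is not None and abs(self.c_in + self.c_out - self.sigma) > _SIGMA_TOL * max(1.0, self.sigma):
            raise ValueError(
                f"{self.name}: c_in + c_out = {self.c_in + self.c_out} "
                f"violates conservation constant sigma = {self.sigma}"
            )

    def with_concentrations(self, c_in: float, c_out: float) -> "IonSpecies":
        return IonSpecies(self.name, self.z, c_in, c_out, self.sigma)


@dataclass(frozen=True)
class MembraneGeometry:
    """Membrane capacitance, surface-to-volume ratio and fixed anions.

    Parameters
    ----------
    Cm_uF_per_cm2 : float
        Specific membrane capacitance, uF/cm^2.
    S_over_v : float
        Surface-to-volume ratio of the cell, 1/m.
    A_in_mM : float
        Intracellular impermeable-anion concentration, mM.  These anions
        carry charge but no current; they set the offset between bulk
        neutrality and the actual membrane potential.
    """

    Cm_uF_per_cm2: float = 1.0
    S_over_v: float = 4.0e5
    A_in_mM: float = 110.0

    def __post_init__(self) -> None:
        if self.Cm_uF_per_cm2 <= 0 or self.S_over_v <= 0 or self.A_in_mM <= 0:
            raise ValueError("Cm, S/v and [A-]i must all be positive")

    @property
    def Cm_F_per_m2(self) -> float:
        return self.Cm_uF_per_cm2 * UF_PER_CM2_TO_F_PER_M2


def _reduced_voltage(z: int, v_mV: float, constants: PhysicalConstants) -> float:
    """u = z F V / (R T), dimensionless."""
    return z * v_mV / constants.vt_mV


def _phi(u: float) -> float:
    """phi(u) = u / (1 - exp(-u)), smooth through u = 0, overflow-safe."""
    if abs(u) < 1e-8:
        return 1.0 + u / 2.0 + u * u / 12.0
    if u > 37.0:
        return u  # e^-u below double precision
    if u < -37.0:
        return -u * math.exp(u)  # underflows smoothly to 0
    return u / (-math.expm1(-u))


def _phi_prime(u: float) -> float:
    """d phi / du."""
    if abs(u) < 1e-6:
        return 0.5 + u / 6.0
    e = -math.expm1(-u)  # 1 - exp(-u)
    return (e - u * math.exp(-u)) / (e * e)


def _phi_double_prime(u: float) -> float:
    """d^2 phi / du^2."""
    if abs(u) < 1e-4:
        return 1.0 / 6.0 - u * u / 60.0
    e = -math.expm1(-u)
    ex = math.exp(-u)
    return (ex * (u - 2.0)) / (e * e) + 2.0 * u * ex * ex / (e * e * e)


def nernst_potential(ion: IonSpecies, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Equilibrium (Nernst) potential E_q = (RT / zF) ln(c_out / c_in), in mV."""
    if ion.c_in <= 0 or ion.c_out <= 0:
        raise ValueError(f"{ion.name}: Nernst potential needs strictly positive concentrations")
    return constants.vt_mV / ion.z * math.log(ion.c_out / ion.c_in)


def intramembrane_profile(
    ion: IonSpecies,
    v_mV: float,
    xi: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Steady-state intramembrane concentration at fractional depth xi.

    xi = 0 is the extracellular face (returns c_out), xi = 1 the
    intracellular face (returns c_in).  V = 0 reduces to the linear profile.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    u = _reduced_voltage(ion.z, v_mV, constants)
    delta = ion.c_in - ion.c_out
    if abs(u) < 1e-8:
        # second-order expansion of expm1(-u*xi)/expm1(-u) about u = 0
        w = xi * (1.0 + u * (1.0 - xi) / 2.0)
    else:
        w = math.expm1(-u * xi) / math.expm1(-u)
    return ion.c_out + delta * w


def harmonic_mean_concentration(
    ion: IonSpecies,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Harmonic mean c̄ of the intramembrane profile, in mM.

    c̄ = d / ∫ dx / c(x), evaluated in closed form:

        c̄ = [c_in - c_out e^{-u}] / [1 - e^{-u}] * V / (V - E_q)

    with u = zFV/RT.  Continuous through both removable singularities
    (V = 0 and V = E_q); both limits are handled by series expansion.
    """
    ci, co = ion.c_in, ion.c_out
    if ci == 0.0 and co == 0.0:
        raise ValueError(f"{ion.name}: at least one boundary concentration must be positive")
    if ci == co:
        return ci
    if ci == 0.0 or co == 0.0:
        # 1/c(x) has a non-integrable boundary only in the limit; the
        # harmonic mean tends to 0 as either bath concentration does.
        return 0.0
    u = _reduced_voltage(ion.z, v_mV, constants)
    uE = math.log(co / ci)  # reduced Nernst voltage z*F*E_q/(R*T)
    delta = ci - co
    # c̄ = (delta*phi(u) + co*u) / (u - uE); numerator and denominator share
    # a simple zero at u = uE, so switch to a 2nd-order series there.
    du = u - uE
    if abs(du) < 4e-8:  # ~1e-6 mV for |z| = 1
        a = delta * _phi_prime(uE) + co
        b = 0.5 * delta * _phi_double_prime(uE)
        return a + b * du
    return (delta * _phi(u) + co * u) / du


def conductance_per_area(
    P: float,
    ion: IonSpecies,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """GNP conductance density G_q = z^2 F^2 P c̄ / (RT), in mS/cm^2.

    P is the (membrane-averaged) permeability in m/s.
    """
    if P < 0:
        raise ValueError("permeability must be nonnegative")
    cbar = harmonic_mean_concentration(ion, v_mV, constants)  # mol/m^3
    g_SI = ion.z ** 2 * constants.F ** 2 * P * cbar / constants.RT
    return g_SI * S_PER_M2_TO_MS_PER_CM2


def ghk_flux_current_density(
    P: float,
    ion: IonSpecies,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """GHK current density in the flux convention, uA/cm^2.

    Positive for net efflux of a cation; equals G_q (V - E_q) with the GNP
    conductance.  The small-V limit is z F P (c_in - c_out).
    """
    if P < 0:
        raise ValueError("permeability must be nonnegative")
    u = _reduced_voltage(ion.z, v_mV, constants)
    delta = ion.c_in - ion.c_out
    # z^2F^2P/(RT) * V * (ci - co e^-u)/(1 - e^-u) == zFP*(delta*phi(u) + co*u)
    i_SI = ion.z * constants.F * P * (delta * _phi(u) + ion.c_out * u)
    return i_SI * A_PER_M2_TO_UA_PER_CM2


def ghk_current_density(
    P: float,
    ion: IonSpecies,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """GHK current in the model convention I_q = -G_q (V - E_q), uA/cm^2.

    This is the sign used by every voltage equation here
    (Cm dV/dt = sum_q I_q): depolarizing currents are positive.
    """
    return -ghk_flux_current_density(P, ion, v_mV, constants)


def voltage_from_charge(
    ions: Sequence[IonSpecies],
    geom: MembraneGeometry = MembraneGeometry(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Membrane potential from the bulk net-charge imbalance, in mV.

        V = (v F) / (2 S Cm) * ( -[A-]_i + sum_q z_q ([q]_i - [q]_o) )

    The prefactor is huge (~1.2e4 mV per mM of imbalance), which is why
    physiological voltages correspond to micromolar charge offsets.
    """
    net = -geom.A_in_mM + sum(ion.z * (ion.c_in - ion.c_out) for ion in ions)
    v_SI = constants.F / (2.0 * geom.S_over_v * geom.Cm_F_per_m2) * net
    return v_SI * 1000.0


def charge_sensitivity_mV_per_mM(
    geom: MembraneGeometry = MembraneGeometry(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """d V / d(net charge concentration): vF/(2 S Cm) in mV per mM."""
    return constants.F / (2.0 * geom.S_over_v * geom.Cm_F_per_m2) * 1000.0
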