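"""Single-channel and whole-membrane channel characterization.

A channel is a pore permeable to one or more ion species, each with its own
single-channel permeability.  Under electrodiffusion the channel's I-V curve
is the sum of per-ion GHK currents, so rectification is a property of the
bath concentrations as much as of the pore: a two-permeant channel is
exactly linear only when the permeability ratio counterbalances the two
concentration gradients (``linearity_ratio``), which is how single-channel
conductances are measured experimentally and therefore how permeabilities
can be recovered from them (``permeabilities_from_linear_conductance``).

Two complementary conductance/reversal decompositions of the same total
current are provided: the *apparent* pair (composite-ion GHK form;
voltage-independent reversal; equal-valence permeants only) and the
*latent* pair (chord-conductance form; both voltage-dependent; any
valences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .core_gnp import (
    IonSpecies,
    ghk_flux_current_density,
    harmonic_mean_concentration,
    nernst_potential,
)

__all__ = [
    "ChannelSpec",
    "pore_cross_section",
    "linearity_ratio",
    "permeabilities_from_linear_conductance",
    "per_ion_conductance",
    "apparent_conductance_reversal",
    "latent_conductance_reversal",
    "single_channel_current",
    "single_channel_iv",
    "membrane_average_permeability",
    "gabaa_channel",
    "ampa_channel",
    "ampa_glur2less_channel",
    "leak_channel",
    "channel_preset",
]

#: conversion: S -> pS
_S_TO_PS = 1e12
#: conversion: A -> pA
_A_TO_PA = 1e12


def pore_cross_section(diameter_m: float) -> float:
    """Effective pore cross-section Sc = pi * d^2 in m^2.

    The calibration convention here takes the effective electrodiffusive
    cross-section as pi*d^2 rather than the geometric disc area pi*(d/2)^2;
    this is the convention under which published 30 pS / 5 Angstrom
    single-channel calibrations and the membrane-averaged permeabilities
    they imply are mutually consistent.
    """
    if diameter_m <= 0:
        raise ValueError("pore diameter must be positive")
    return math.pi * diameter_m ** 2


@dataclass(frozen=True)
class ChannelSpec:
    """A channel: ordered permeants with single-channel permeabilities.

    Parameters
    ----------
    name : str
    permeants : sequence of (IonSpecies, P)
        P is the single-channel permeability in m/s (>= 0).
    Sc : float
        Pore cross-section, m^2.
    density_per_cm2 : float, optional
        Channels per cm^2 of membrane, for membrane averaging.
    """

    name: str
    permeants: Tuple[Tuple[IonSpecies, float], ...]
    Sc: float
    density_per_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.permeants) < 1:
            raise ValueError("a channel needs at least one permeant")
        if self.Sc <= 0:
            raise ValueError("pore cross-section must be positive")
        for ion, P in self.permeants:
            if P < 0:
                raise ValueError(f"{self.name}/{ion.name}: permeability must be nonnegative")
        object.__setattr__(self, "permeants", tuple(self.permeants))

    @property
    def ions(self) -> List[IonSpecies]:
        return [ion for ion, _ in self.permeants]

    def with_permeants(self, permeants: Sequence[Tuple[IonSpecies, float]]) -> "ChannelSpec":
        return ChannelSpec(self.name, tuple(permeants), self.Sc, self.density_per_cm2)


def linearity_ratio(ion1: IonSpecies, ion2: IonSpecies) -> float:
    """Permeability ratio P2/P1 that makes a two-permeant I-V exactly linear.

        P2/P1 = -([q1]_i - [q1]_o) / ([q2]_i - [q2]_o)

    The two Goldman rectifications cancel only when the gradients oppose in
    this proportion; a gradient-free q2 cannot compensate any q1 gradient.
    """
    d2 = ion2.c_in - ion2.c_out
    if d2 == 0.0:
        raise ZeroDivisionError(
            f"{ion2.name} has no concentration gradient and cannot counterbalance {ion1.name}"
        )
    return -(ion1.c_in - ion1.c_out) / d2


def permeabilities_from_linear_conductance(
    gc_m_pS: float,
    spec: ChannelSpec,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[float, float]:
    """Invert a measured linear slope gc_m into the two permeabilities (m/s).

        P1 = RT gc_m / (Sc F^2) * ([q2]_i - [q2]_o) / ([q1]_o [q2]_i - [q2]_o [q1]_i)
        P2 = RT gc_m / (Sc F^2) * ([q1]_o - [q1]_i) / ([q1]_o [q2]_i - [q2]_o [q1]_i)

    Valid when the baths satisfy the linearity condition; the returned pair
    reproduces gc_m as the (constant) slope of the channel's total I-V.
    """
    if gc_m_pS <= 0:
        raise ValueError("measured conductance must be positive")
    if len(spec.permeants) != 2:
        raise ValueError("calibration requires exactly two permeants")
    (i1, _), (i2, _) = spec.permeants
    det = i1.c_out * i2.c_in - i2.c_out * i1.c_in
    if det == 0.0:
        raise ValueError("degenerate concentration determinant; permeabilities not identifiable")
    pref = constants.RT * (gc_m_pS / _S_TO_PS) / (spec.Sc * constants.F ** 2)
    P1 = pref * (i2.c_in - i2.c_out) / det
    P2 = pref * (i1.c_out - i1.c_in) / det
    return P1, P2


def per_ion_conductance(
    spec: ChannelSpec,
    ion_index: int,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Single-channel conductance g_q = Sc F^2 P_q c̄_q / RT for one permeant, pS."""
    ion, P = spec.permeants[ion_index]
    cbar = harmonic_mean_concentration(ion, v_mV, constants)
    g = spec.Sc * ion.z ** 2 * constants.F ** 2 * P * cbar / constants.RT
    return g * _S_TO_PS


def _composite_ion(spec: ChannelSpec, reference_index: int = 0) -> IonSpecies:
    """Composite permeant [C] = [q1] + sum_k (Pk/P1) [qk] for equal-valence channels."""
    zs = {ion.z for ion, _ in spec.permeants}
    if len(zs) != 1 or abs(next(iter(zs))) != 1:
        raise ValueError(
            f"{spec.name}: apparent conductance/reversal is defined only for "
            "channels whose permeants all share the same unit valence"
        )
    zC = next(iter(zs))
    ref_ion, ref_P = spec.permeants[reference_index]
    if ref_P <= 0:
        raise ValueError("reference permeant must have positive permeability")
    ci = sum(P / ref_P * ion.c_in for ion, P in spec.permeants)
    co = sum(P / ref_P * ion.c_out for ion, P in spec.permeants)
    return IonSpecies(f"{spec.name}:C", zC, ci, co)


def apparent_conductance_reversal(
    spec: ChannelSpec,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    reference_index: int = 0,
) -> Tuple[float, float]:
    """Apparent pair (gc_a in pS, Ec_a in mV).

    gc_a = Sc F^2 P1 c̄_C / RT with the composite permeant C; Ec_a is the
    Nernst potential of C, independent of V, and is the channel's true
    zero-current voltage.  The result does not depend on which permeant is
    chosen as reference.  Mixed-valence channels have no apparent form.
    """
    comp = _composite_ion(spec, reference_index)
    _, ref_P = spec.permeants[reference_index]
    cbar = harmonic_mean_concentration(comp, v_mV, constants)
    gc_a = spec.Sc * constants.F ** 2 * ref_P * cbar / constants.RT * _S_TO_PS
    Ec_a = nernst_potential(comp, constants)
    return gc_a, Ec_a


def latent_conductance_reversal(
    spec: ChannelSpec,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[float, float]:
    """Latent (chord-conductance) pair (gc_l in pS, Ec_l in mV).

    gc_l = sum_q g_q and Ec_l = sum_q g_q E_q / gc_l.  Valid for any mix of
    valences, and -gc_l (V - Ec_l) reproduces the total current at every V;
    the price is that both members are voltage-dependent even for channels
    with perfectly linear I-V curves.
    """
    gs, Es = [], []
    for k, (ion, _) in enumerate(spec.permeants):
        gs.append(per_ion_conductance(spec, k, v_mV, constants))
        Es.append(nernst_potential(ion, constants))
    gc_l = sum(gs)
    if gc_l == 0.0:
        return 0.0, math.nan
    Ec_l = sum(g * E for g, E in zip(gs, Es)) / gc_l
    return gc_l, Ec_l


def single_channel_current(
    spec: ChannelSpec,
    v_mV: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[List[float], float]:
    """Per-ion and total single-channel currents at V, in pA (model sign).

    Each per-ion current is the Sc-scaled GHK current density; positive
    values depolarize (I = -g (V - E) convention).
    """
    per_ion = []
    for ion, P in spec.permeants:
        i_SI = -ghk_flux_current_density(P, ion, v_mV, constants) / 100.0  # back to A/m^2
        per_ion.append(i_SI * spec.Sc * _A_TO_PA)
    return per_ion, sum(per_ion)


def single_channel_iv(
    spec: ChannelSpec,
    v_grid_mV: Sequence[float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """I-V table over a voltage grid.

    Columns: ``V_mV``, one ``I_<ion>_pA`` per permeant, ``I_total_pA``,
    ``gc_a_pS``/``Ec_a_mV`` (NaN where the apparent form is undefined) and
    ``gc_l_pS``/``Ec_l_mV``.  Currents use the model sign convention; flip
    the sign of the current columns to match the experimental plotting
    convention (-i).
    """
    rows = []
    try:
        _composite_ion(spec)
        has_apparent = True
    except ValueError:
        has_apparent = False
    for v in np.asarray(v_grid_mV, dtype=float):
        if not np.isfinite(v):
            raise ValueError("voltage grid must be finite")
        per_ion, total = single_channel_current(spec, v, constants)
        if has_apparent:
            gc_a, Ec_a = apparent_conductance_reversal(spec, v, constants)
        else:
            gc_a, Ec_a = math.nan, math.nan
        gc_l, Ec_l = latent_conductance_reversal(spec, v, constants)
        row = {"V_mV": v}
        for (ion, _), i in zip(spec.permeants, per_ion):
            row[f"I_{ion.name}_pA"] = i
        row.update(I_total_pA=total, gc_a_pS=gc_a, Ec_a_mV=Ec_a, gc_l_pS=gc_l, Ec_l_mV=Ec_l)
        rows.append(row)
    return pd.DataFrame(rows)


def membrane_average_permeability(
    single_channel_P: float,
    density_per_cm2: float,
    Sc: float,
    open_probability: float = 1.0,
) -> float:
    """Membrane-averaged permeability P = (Nc/S) Sc P po, in m/s.

    density is channels per cm^2; Sc in m^2; po in [0, 1].
    """
    if density_per_cm2 < 0:
        raise ValueError("channel density must be nonnegative")
    if not 0.0 <= open_probability <= 1.0:
        raise ValueError("open probability must lie in [0, 1]")
    density_per_m2 = density_per_cm2 * 1e4
    return density_per_m2 * Sc * single_channel_P * open_probability


# ---------------------------------------------------------------------------
# Presets.  Bath concentrations are the physiological set used throughout the
# neuron models; permeabilities are recovered from published 30 pS linear-
# condition calibrations at the calibration baths, then applied at the
# physiological baths.
# ---------------------------------------------------------------------------

PORE_DIAMETER_M = 5e-10  # 5 Angstrom, both GABAA and AMPA
_SC = pore_cross_section(PORE_DIAMETER_M)

#: physiological bath concentrations (mM)
PHYSIOLOGICAL = {
    "K": (96.83, 3.17),
    "Na": (23.58, 131.42),
    "Cl": (10.41, 134.59),
    "HCO3": (15.0, 25.0),
    "Ca": (1e-4, 2.0),
}

#: single-channel permeability of the equivalent leak channel (m/s)
LEAK_SINGLE_CHANNEL_P = {"K": 2.55e-1, "Na": 1.27e-2, "Cl": 5.08e-2}
LEAK_DENSITY_PER_CM2 = 1e7
AMPA_DENSITY_PER_CM2 = 4e6
#: calcium permeability of the GluR2-lacking AMPA channel (m/s)
P_CA_GLUR2LESS = 2.70


def _phys_ion(name: str, z: int) -> IonSpecies:
    ci, co = PHYSIOLOGICAL[name]
    return IonSpecies(name, z, ci, co)


def gabaa_channel(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ChannelSpec:
    """GABAA receptor channel (Cl-, HCO3-) at physiological baths.

    Permeabilities are calibrated from the 30 pS linear I-V measured with
    symmetric-high chloride ([Cl]i = 147, [Cl]o = 145 mM; the 2 mM excess is
    what the HCO3 gradient requires for exact linearity at ratio 0.2).
    """
    cal_cl = IonSpecies("Cl", -1, 147.0, 145.0)
    cal_hco3 = IonSpecies("HCO3", -1, 15.0, 25.0)
    cal = ChannelSpec("GABAA", ((cal_cl, 1.0), (cal_hco3, 0.2)), _SC)
    P_cl, P_hco3 = permeabilities_from_linear_conductance(30.0, cal, constants)
    return ChannelSpec(
        "GABAA",
        ((_phys_ion("Cl", -1), P_cl), (_phys_ion("HCO3", -1), P_hco3)),
        _SC,
    )


def ampa_channel(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ChannelSpec:
    """GluR2-containing AMPA channel (K+, Na+), linear at physiological baths."""
    k = _phys_ion("K", 1)
    na = _phys_ion("Na", 1)
    cal = ChannelSpec("AMPA", ((k, 1.0), (na, linearity_ratio(k, na))), _SC)
    P_k, P_na = permeabilities_from_linear_conductance(30.0, cal, constants)
    return ChannelSpec(
        "AMPA", ((k, P_k), (na, P_na)), _SC, density_per_cm2=AMPA_DENSITY_PER_CM2
    )


def ampa_glur2less_channel(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ChannelSpec:
    """GluR2-lacking AMPA channel: the GluR2-containing spec plus a large
    calcium permeability, which breaks the K/Na counterbalance and makes the
    channel inwardly rectifying."""
    base = ampa_channel(constants)
    ca = _phys_ion("Ca", 2)
    return ChannelSpec(
        "AMPA-GluR2less",
        base.permeants + ((ca, P_CA_GLUR2LESS),),
        base.Sc,
        density_per_cm2=base.density_per_cm2,
    )


def leak_channel() -> ChannelSpec:
    """Equivalent leak channel (K+, Na+, Cl-), outwardly rectifying."""
    return ChannelSpec(
        "leak",
        (
            (_phys_ion("K", 1), LEAK_SINGLE_CHANNEL_P["K"]),
            (_phys_ion("Na", 1), LEAK_SINGLE_CHANNEL_P["Na"]),
            (_phys_ion("Cl", -1), LEAK_SINGLE_CHANNEL_P["Cl"]),
        ),
        _SC,
        density_per_cm2=LEAK_DENSITY_PER_CM2,
    )


def channel_preset(name: str, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ChannelSpec:
    """Look up a channel preset: gabaa, ampa, ampa-glur2less or leak."""
    presets = {
        "gabaa": gabaa_channel,
        "ampa": ampa_channel,
        "ampa-glur2less": ampa_glur2less_channel,
        "leak": lambda constants=constants: leak_channel(),
    }
    key = name.lower()
    if key not in presets:
        raise KeyError(f"unknown channel preset {name!r}; choose from {sorted(presets)}")
    return presets[key](constants) if key != "leak" else leak_channel()
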