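"""The seven neurodynamic model variants over a uniform state vector.

Variants
--------
========  ======================  ========  ===========  ==================
variant   dynamic state           leak      glutamate    voltage-gated
========  ======================  ========  ===========  ==================
chh       V, m, h, n              linear    linear       circuit (RTM)
fgnp      V, m, h, n              GHK*      linear       circuit (RTM)
gnp       Ko, Nai, Cli, m, h, n   GHK       GHK          circuit (RTM)
vgnp      Ko, Nai, Cli, m, h, n   GHK       GHK          GHK/f_q (both)
kvgnp     Ko, Nai, Cli, m, h, n   GHK       GHK          GHK/f_K (K only)
navgnp    Ko, Nai, Cli, m, h, n   GHK       GHK          GHK/f_Na (Na only)
ihh       V, Ko, Nai, Cli, m,h,n  linear    linear       circuit (RTM)
========  ======================  ========  ===========  ==================

(* at concentrations frozen to the reference steady state)

In the GNP family the membrane potential is not a dynamic variable: it is
algebraically slaved to the concentrations through the charge relation
V = vF/(2 S Cm) (-[A-]_i + sum_q z_q([q]_i - [q]_o)) and is recomputed
inside every derivative evaluation.  The complementary concentrations
follow from the closed-system conservation constants sigma_q.

The chloride balance is d[Cl-]_i/dt = -(S/vF) I_ClL in the
depolarizing-positive current convention used throughout (chloride influx,
which hyperpolarizes, raises [Cl-]_i); this is the direction consistent
with the charge-voltage relation above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .core_gnp import (
    IonSpecies,
    MembraneGeometry,
    ghk_current_density,
    harmonic_mean_concentration,
    nernst_potential,
    voltage_from_charge,
)
from .gating_pumps import (
    FqFit,
    GateState,
    PRINTED_FQ_COEFFICIENTS,
    PumpSpec,
    StimulusProtocol,
    gate_derivatives,
    gate_steady_state,
    pump_current,
)

__all__ = [
    "VARIANTS",
    "GNP_FAMILY",
    "ModelDefinition",
    "complement_concentrations",
    "steady_state_leak_linearization",
    "glutamate_linearization",
    "membrane_voltage",
    "rhs",
    "make_rhs",
    "currents",
    "state_names",
    "pack_state",
    "unpack_state",
]

VARIANTS = ("chh", "fgnp", "gnp", "vgnp", "kvgnp", "navgnp", "ihh")
#: variants whose voltage is algebraic in the concentrations
GNP_FAMILY = ("gnp", "vgnp", "kvgnp", "navgnp")

ION_VALENCE = {"K": 1, "Na": 1, "Cl": -1}

#: canonical conservation constants sigma_q = [q]_i + [q]_o (mM)
DEFAULT_SIGMA = {"K": 100.0, "Na": 155.0, "Cl": 145.0}

#: canonical reference steady state (mM / mV)
DEFAULT_REFERENCE = {"Ko": 3.17, "Nai": 23.58, "Cli": 10.41, "V": -68.17}

#: membrane-averaged leak permeabilities (m/s)
DEFAULT_P_LEAK = {"K": 2.00e-8, "Na": 1.00e-9, "Cl": 4.00e-9}
#: membrane-averaged glutamate (AMPA) permeabilities at po = 1 (m/s),
#: calibrated so the canonical phasic episode reproduces the documented
#: ~20% pump-current excursion (see docs/methods.md)
DEFAULT_P_GLU = {"K": 8.46e-9, "Na": 7.35e-9}
#: membrane-averaged voltage-gated permeabilities (m/s)
DEFAULT_P_GATED = {"K": 1.70e-6, "Na": 1.47e-6}

#: published iHH glutamatergic conductance pair (mS/cm^2); the model default
#: derives the pair from the per-ion GHK linearization instead (see
#: ModelDefinition.gg_ihh), keeping the iHH drive consistent with the GNP
#: family it is compared against
PRINTED_GG_IHH = {"K": 0.12, "Na": 0.03}


def complement_concentrations(
    Ko: float, Nai: float, Cli: float, sigma: Mapping[str, float] = DEFAULT_SIGMA
) -> Dict[str, float]:
    """Full concentration table from the three dynamic concentrations.

    Returns all six bulk concentrations; complements that fall below zero
    are returned as-is so callers (notably the continuation code) can flag
    the state as unphysical rather than silently clipping it.
    """
    return {
        "Ko": Ko,
        "Ki": sigma["K"] - Ko,
        "Nai": Nai,
        "Nao": sigma["Na"] - Nai,
        "Cli": Cli,
        "Clo": sigma["Cl"] - Cli,
    }


@dataclass(frozen=True)
class ModelDefinition:
    """A model variant with its full parameter set.

    All parameters default to the canonical set; the linearized leak
    constants of the cHH and iHH variants (GLH, ELH, per-ion G_qL) are
    derived from the GNP leak at the reference steady state once, at
    construction, and frozen.
    """

    variant: str = "gnp"
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    geometry: MembraneGeometry = MembraneGeometry()
    sigma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    P_leak: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_LEAK))
    P_glu: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_GLU))
    P_gated: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_GATED))
    GKM: float = 20.0
    GNaM: float = 30.0
    GG_iHH: Optional[Mapping[str, float]] = None
    pump: PumpSpec = PumpSpec()
    stimulus: StimulusProtocol = StimulusProtocol()
    fq_coefficients: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(PRINTED_FQ_COEFFICIENTS)
    )
    reference_state: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_REFERENCE))

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for name, sig in self.sigma.items():
            if sig <= 0:
                raise ValueError(f"sigma_{name} must be positive")

    # -- reference-state helpers -------------------------------------------

    def reference_ions(self) -> Dict[str, IonSpecies]:
        """IonSpecies at the reference steady-state concentrations."""
        c = complement_concentrations(
            self.reference_state["Ko"], self.reference_state["Nai"], self.reference_state["Cli"], self.sigma
        )
        return {
            "K": IonSpecies("K", 1, c["Ki"], c["Ko"]),
            "Na": IonSpecies("Na", 1, c["Nai"], c["Nao"]),
            "Cl": IonSpecies("Cl", -1, c["Cli"], c["Clo"]),
        }

    def gg_ihh(self) -> Dict[str, float]:
        """iHH glutamatergic conductances: the explicit override, or the
        per-ion GHK glutamate conductance frozen at the reference state."""
        if self.GG_iHH is not None:
            return dict(self.GG_iHH)
        ions = self.reference_ions()
        v = self.reference_state["V"]
        out = {}
        for name in ("K", "Na"):
            cbar = harmonic_mean_concentration(ions[name], v, self.constants)
            out[name] = self.constants.F ** 2 * self.P_glu[name] * cbar / self.constants.RT * 0.1
        return out

    def fq(self, ion_name: str) -> FqFit:
        return FqFit(tuple(self.fq_coefficients[ion_name]), ion_name)

    def with_(self, **kwargs) -> "ModelDefinition":
        """Return a copy with fields replaced (dataclasses.replace wrapper)."""
        return replace(self, **kwargs)


def steady_state_leak_linearization(
    defn: ModelDefinition,
) -> Tuple[float, float, Dict[str, float]]:
    """Linearize the GNP leak at the reference steady state.

    Returns ``(GLH, ELH, G_leak)`` where ``G_leak`` maps ion name to the
    per-ion leak conductance density (mS/cm^2) used as the frozen iHH
    constants, GLH is their sum and ELH the conductance-weighted mean of
    the Nernst potentials (the latent pair of the whole-membrane leak).
    """
    ions = defn.reference_ions()
    v = defn.reference_state["V"]
    G: Dict[str, float] = {}
    E: Dict[str, float] = {}
    for name, ion in ions.items():
        cbar = harmonic_mean_concentration(ion, v, defn.constants)
        G[name] = ion.z ** 2 * defn.constants.F ** 2 * defn.P_leak[name] * cbar / defn.constants.RT * 0.1
        E[name] = nernst_potential(ion, defn.constants)
    GLH = sum(G.values())
    ELH = sum(G[k] * E[k] for k in G) / GLH
    return GLH, ELH, G


def glutamate_linearization(defn: ModelDefinition) -> Tuple[float, float]:
    """Apparent (composite-ion) conductance and reversal of the GHK
    glutamate current at the reference steady state: (Gglu mS/cm^2, Eglu mV).

    The canonical permeability ratio sits at the linearity condition, so
    Gglu is constant in V and Eglu ~ 0 mV.
    """
    ions = defn.reference_ions()
    r = defn.P_glu["Na"] / defn.P_glu["K"]
    comp = IonSpecies(
        "C",
        1,
        ions["K"].c_in + r * ions["Na"].c_in,
        ions["K"].c_out + r * ions["Na"].c_out,
    )
    cbar = harmonic_mean_concentration(comp, defn.reference_state["V"], defn.constants)
    Gglu = defn.constants.F ** 2 * defn.P_glu["K"] * cbar / defn.constants.RT * 0.1
    return Gglu, nernst_potential(comp, defn.constants)


# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

def state_names(variant: str) -> Tuple[str, ...]:
    """Index map of the flat state vector for a variant."""
    if variant in GNP_FAMILY:
        return ("Ko", "Nai", "Cli", "m", "h", "n")
    if variant in ("chh", "fgnp"):
        return ("V", "m", "h", "n")
    if variant == "ihh":
        return ("V", "Ko", "Nai", "Cli", "m", "h", "n")
    raise ValueError(f"unknown variant {variant!r}")


def pack_state(variant: str, **values: float) -> np.ndarray:
    return np.array([values[k] for k in state_names(variant)], dtype=float)


def unpack_state(variant: str, y: np.ndarray) -> Dict[str, float]:
    return dict(zip(state_names(variant), np.asarray(y, dtype=float)))


def membrane_voltage(defn: ModelDefinition, Ko: float, Nai: float, Cli: float) -> float:
    """Algebraic membrane potential of the GNP family from concentrations.

    Evaluated directly from the linear charge relation (no physicality
    checks: continuation deliberately probes states with negative
    complements and flags them downstream).
    """
    c = complement_concentrations(Ko, Nai, Cli, defn.sigma)
    geom, cst = defn.geometry, defn.constants
    net = -geom.A_in_mM + (c["Ki"] - c["Ko"]) + (c["Nai"] - c["Nao"]) - (c["Cli"] - c["Clo"])
    return cst.F / (2.0 * geom.S_over_v * geom.Cm_F_per_m2) * net * 1000.0


# ---------------------------------------------------------------------------
# Current evaluation and derivative functions
# ---------------------------------------------------------------------------

def currents(
    defn: ModelDefinition, t_ms: float, y: np.ndarray, po: Optional[float] = None
) -> Dict[str, float]:
    """All membrane currents (uA/cm^2, depolarizing-positive) plus V at a state.

    Keys: per-ion ``IKV INaV IKL INaL IClL IKG INaG``, pump ``INaK``,
    family sums ``IV IL IG`` and ``Idiff = IV + IL + IG``, and ``V_mV``.
    ``po`` overrides the stimulus protocol when given.
    """
    v = defn.variant
    s = unpack_state(v, y)
    cst, geom = defn.constants, defn.geometry
    if po is None:
        po = defn.stimulus.po(t_ms)

    if v in ("chh", "fgnp"):
        ions = defn.reference_ions()
        Ko, Nai = defn.reference_state["Ko"], defn.reference_state["Nai"]
        V = s["V"]
    else:
        c = complement_concentrations(s["Ko"], s["Nai"], s["Cli"], defn.sigma)
        ions = {
            "K": IonSpecies("K", 1, c["Ki"], c["Ko"]),
            "Na": IonSpecies("Na", 1, c["Nai"], c["Nao"]),
            "Cl": IonSpecies("Cl", -1, c["Cli"], c["Clo"]),
        }
        Ko, Nai = s["Ko"], s["Nai"]
        V = s["V"] if v == "ihh" else voltage_from_charge(list(ions.values()), geom, cst)

    EK = nernst_potential(ions["K"], cst)
    ENa = nernst_potential(ions["Na"], cst)
    ECl = nernst_potential(ions["Cl"], cst)
    gates = GateState(s["m"], s["h"], s["n"])
    nk_gate = gates.n ** 4
    na_gate = gates.m ** 3 * gates.h

    # voltage-gated
    k_fmt = "ghk" if v in ("vgnp", "kvgnp") else "rtm"
    na_fmt = "ghk" if v in ("vgnp", "navgnp") else "rtm"
    if k_fmt == "rtm":
        IKV = -defn.GKM * nk_gate * (V - EK)
    else:
        IKV = nk_gate * ghk_current_density(defn.P_gated["K"], ions["K"], V, cst) / defn.fq("K")(V)
    if na_fmt == "rtm":
        INaV = -defn.GNaM * na_gate * (V - ENa)
    else:
        INaV = na_gate * ghk_current_density(defn.P_gated["Na"], ions["Na"], V, cst) / defn.fq("Na")(V)

    # leak
    if v in ("chh",):
        GLH, ELH, _ = steady_state_leak_linearization(defn)
        IKL = INaL = 0.0
        IClL = 0.0
        IL = -GLH * (V - ELH)
    elif v == "ihh":
        _, _, Gl = steady_state_leak_linearization(defn)
        IKL = -Gl["K"] * (V - EK)
        INaL = -Gl["Na"] * (V - ENa)
        IClL = -Gl["Cl"] * (V - ECl)
        IL = IKL + INaL + IClL
    else:
        IKL = ghk_current_density(defn.P_leak["K"], ions["K"], V, cst)
        INaL = ghk_current_density(defn.P_leak["Na"], ions["Na"], V, cst)
        IClL = ghk_current_density(defn.P_leak["Cl"], ions["Cl"], V, cst)
        IL = IKL + INaL + IClL

    # glutamate
    if v in ("chh", "fgnp"):
        Gglu, Eglu = glutamate_linearization(defn)
        IKG = INaG = 0.0
        IG = -po * Gglu * (V - Eglu)
    elif v == "ihh":
        gg = defn.gg_ihh()
        IKG = -po * gg["K"] * (V - EK)
        INaG = -po * gg["Na"] * (V - ENa)
        IG = IKG + INaG
    else:
        IKG = po * ghk_current_density(defn.P_glu["K"], ions["K"], V, cst)
        INaG = po * ghk_current_density(defn.P_glu["Na"], ions["Na"], V, cst)
        IG = IKG + INaG

    INaK = pump_current(Nai, Ko, defn.pump, geom.S_over_v, cst)
    IV = IKV + INaV
    return {
        "V_mV": V,
        "IKV": IKV,
        "INaV": INaV,
        "IKL": IKL,
        "INaL": INaL,
        "IClL": IClL,
        "IKG": IKG,
        "INaG": INaG,
        "INaK": INaK,
        "IV": IV,
        "IL": IL,
        "IG": IG,
        "Idiff": IV + IL + IG,
        "EK": EK,
        "ENa": ENa,
        "ECl": ECl,
    }


def rhs(defn: ModelDefinition, t_ms: float, y: np.ndarray, po: Optional[float] = None) -> np.ndarray:
    """Time derivative of the variant's state vector (units per ms)."""
    v = defn.variant
    s = unpack_state(v, y)
    cur = currents(defn, t_ms, y, po)
    V = cur["V_mV"]
    dm, dh, dn = gate_derivatives(V, s["m"], s["h"], s["n"])

    # mM/ms per uA/cm^2 of current: (S/v) / F, with unit conversions
    cf = defn.geometry.S_over_v / (defn.constants.F * 1e5)

    if v in ("chh", "fgnp"):
        dV = (cur["IV"] + cur["IG"] + cur["IL"] + cur["INaK"]) / defn.geometry.Cm_uF_per_cm2
        return np.array([dV, dm, dh, dn])

    dKo = cf * (-cur["IKV"] - cur["IKL"] - cur["IKG"] + 2.0 * cur["INaK"])
    dNai = cf * (cur["INaV"] + cur["INaL"] + cur["INaG"] + 3.0 * cur["INaK"])
    dCli = -cf * cur["IClL"]
    if v == "ihh":
        dV = (cur["IV"] + cur["IG"] + cur["IL"] + cur["INaK"]) / defn.geometry.Cm_uF_per_cm2
        return np.array([dV, dKo, dNai, dCli, dm, dh, dn])
    return np.array([dKo, dNai, dCli, dm, dh, dn])


def make_rhs(defn: ModelDefinition) -> Callable[[float, np.ndarray], np.ndarray]:
    """A solver-ready derivative function f(t, y) for the variant.

    This is a specialised closure: the variant dispatch, parameter lookups
    and dataclass construction of the generic :func:`rhs` are hoisted out of
    the inner loop, which matters for the long (minutes of model time)
    integrations.  It computes identical derivatives to :func:`rhs`.
    """
    v = defn.variant
    cst, geom = defn.constants, defn.geometry
    F, RT = cst.F, cst.RT
    vt = cst.vt_mV
    sigK, sigNa, sigCl = defn.sigma["K"], defn.sigma["Na"], defn.sigma["Cl"]
    PKL, PNaL, PClL = defn.P_leak["K"], defn.P_leak["Na"], defn.P_leak["Cl"]
    PKG, PNaG = defn.P_glu["K"], defn.P_glu["Na"]
    PKV, PNaV = defn.P_gated["K"], defn.P_gated["Na"]
    GKM, GNaM = defn.GKM, defn.GNaM
    Cm = defn.geometry.Cm_uF_per_cm2
    cf = geom.S_over_v / (F * 1e5)
    vcoef = F / (2.0 * geom.S_over_v * geom.Cm_F_per_m2) * 1000.0  # mV per mM net charge
    A_in = geom.A_in_mM
    po_of_t = defn.stimulus.po
    pump_mode = defn.pump.mode
    I_const = defn.pump.I_const_uA_per_cm2
    pump_ceiling = (
        defn.pump.ceiling_uA_per_cm2(geom.S_over_v, cst)
        if pump_mode == "concentration_dependent"
        else 0.0
    )
    k_ghk = v in ("vgnp", "kvgnp")
    na_ghk = v in ("vgnp", "navgnp")

    def ghk_model(P: float, z: int, ci: float, co: float, V: float) -> float:
        """-zFP(dc*phi(u) + co*u) in uA/cm^2 (scalar, inlined for speed)."""
        u = z * V / vt
        if abs(u) < 1e-8:
            phi = 1.0 + u * (0.5 + u / 12.0)
        elif u > 37.0:
            phi = u
        elif u < -37.0:
            phi = -u * math.exp(u)
        else:
            phi = u / (-math.expm1(-u))
        return -z * F * P * ((ci - co) * phi + co * u) * 100.0

    def rates_and_dgates(V: float, m: float, h: float, n: float):
        x = V + 54.0
        am = 1.28 + 0.16 * x + x * x / 150.0 if abs(x) < 1e-6 else 0.32 * x / (-math.expm1(-x / 4.0))
        x = -(V + 27.0)
        bm = 1.4 + 0.14 * x + 0.28 * x * x / 60.0 if abs(x) < 1e-6 else 0.28 * x / (-math.expm1(-x / 5.0))
        ah = 0.128 * math.exp(-(V + 50.0) / 18.0)
        bh = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
        x = V + 52.0
        an = 0.16 + 0.016 * x + 0.032 * x * x / 60.0 if abs(x) < 1e-6 else 0.032 * x / (-math.expm1(-x / 5.0))
        bn = 0.5 * math.exp(-(V + 57.0) / 40.0)
        return am * (1.0 - m) - bm * m, ah * (1.0 - h) - bh * h, an * (1.0 - n) - bn * n

    if v in ("chh", "fgnp"):
        ions = defn.reference_ions()
        Ki, Ko = ions["K"].c_in, ions["K"].c_out
        Nai, Nao = ions["Na"].c_in, ions["Na"].c_out
        Cli, Clo = ions["Cl"].c_in, ions["Cl"].c_out
        EK = vt * math.log(Ko / Ki)
        ENa = vt * math.log(Nao / Nai)
        ECl = -vt * math.log(Clo / Cli)
        Gglu, Eglu = glutamate_linearization(defn)
        if v == "chh":
            GLH, ELH, _ = steady_state_leak_linearization(defn)
        if pump_mode == "constant":
            INaK0 = I_const
        else:
            INaK0 = -pump_ceiling / (1.0 + math.exp((25.0 - Nai) / 3.0)) / (1.0 + math.exp(3.5 - Ko))

        def f_fixedconc(t: float, y: np.ndarray) -> np.ndarray:
            V, m, h, n = y
            IV = -GKM * n ** 4 * (V - EK) - GNaM * m ** 3 * h * (V - ENa)
            if v == "chh":
                IL = -GLH * (V - ELH)
            else:
                IL = (
                    ghk_model(PKL, 1, Ki, Ko, V)
                    + ghk_model(PNaL, 1, Nai, Nao, V)
                    + ghk_model(PClL, -1, Cli, Clo, V)
                )
            IG = -po_of_t(t) * Gglu * (V - Eglu)
            dm, dh, dn = rates_and_dgates(V, m, h, n)
            return np.array([(IV + IG + IL + INaK0) / Cm, dm, dh, dn])

        return f_fixedconc

    if v == "ihh":
        _, _, Gl = steady_state_leak_linearization(defn)
        GKL_c, GNaL_c, GClL_c = Gl["K"], Gl["Na"], Gl["Cl"]
        gg = defn.gg_ihh()
        GKG_c, GNaG_c = gg["K"], gg["Na"]

        def f_ihh(t: float, y: np.ndarray) -> np.ndarray:
            V, Ko, Nai, Cli, m, h, n = y
            Ki, Nao, Clo = sigK - Ko, sigNa - Nai, sigCl - Cli
            EK = vt * math.log(Ko / Ki)
            ENa = vt * math.log(Nao / Nai)
            ECl = -vt * math.log(Clo / Cli)
            IKV = -GKM * n ** 4 * (V - EK)
            INaV = -GNaM * m ** 3 * h * (V - ENa)
            IKL = -GKL_c * (V - EK)
            INaL = -GNaL_c * (V - ENa)
            IClL = -GClL_c * (V - ECl)
            po = po_of_t(t)
            IKG = -po * GKG_c * (V - EK)
            INaG = -po * GNaG_c * (V - ENa)
            if pump_mode == "constant":
                INaK = I_const
            else:
                INaK = -pump_ceiling / (1.0 + math.exp((25.0 - Nai) / 3.0)) / (1.0 + math.exp(3.5 - Ko))
            dV = (IKV + INaV + IKL + INaL + IClL + IKG + INaG + INaK) / Cm
            dKo = cf * (-IKV - IKL - IKG + 2.0 * INaK)
            dNai = cf * (INaV + INaL + INaG + 3.0 * INaK)
            dCli = -cf * IClL
            dm, dh, dn = rates_and_dgates(V, m, h, n)
            return np.array([dV, dKo, dNai, dCli, dm, dh, dn])

        return f_ihh

    # GNP family
    fK_c = tuple(defn.fq_coefficients["K"]) if k_ghk else None
    fNa_c = tuple(defn.fq_coefficients["Na"]) if na_ghk else None

    def f_gnp(t: float, y: np.ndarray) -> np.ndarray:
        Ko, Nai, Cli, m, h, n = y
        Ki, Nao, Clo = sigK - Ko, sigNa - Nai, sigCl - Cli
        V = vcoef * (-A_in + (Ki - Ko) + (Nai - Nao) - (Cli - Clo))
        IKL = ghk_model(PKL, 1, Ki, Ko, V)
        INaL = ghk_model(PNaL, 1, Nai, Nao, V)
        IClL = ghk_model(PClL, -1, Cli, Clo, V)
        po = po_of_t(t)
        if po:
            IKG = po * ghk_model(PKG, 1, Ki, Ko, V)
            INaG = po * ghk_model(PNaG, 1, Nai, Nao, V)
        else:
            IKG = INaG = 0.0
        if k_ghk:
            n3, n2, n1, n0 = fK_c
            IKV = n ** 4 * ghk_model(PKV, 1, Ki, Ko, V) / (((n3 * V + n2) * V + n1) * V + n0)
        else:
            IKV = -GKM * n ** 4 * (V - vt * math.log(Ko / Ki))
        if na_ghk:
            n3, n2, n1, n0 = fNa_c
            INaV = m ** 3 * h * ghk_model(PNaV, 1, Nai, Nao, V) / (((n3 * V + n2) * V + n1) * V + n0)
        else:
            INaV = -GNaM * m ** 3 * h * (V - vt * math.log(Nao / Nai))
        if pump_mode == "constant":
            INaK = I_const
        else:
            INaK = -pump_ceiling / (1.0 + math.exp((25.0 - Nai) / 3.0)) / (1.0 + math.exp(3.5 - Ko))
        dKo = cf * (-IKV - IKL - IKG + 2.0 * INaK)
        dNai = cf * (INaV + INaL + INaG + 3.0 * INaK)
        dCli = -cf * IClL
        dm, dh, dn = rates_and_dgates(V, m, h, n)
        return np.array([dKo, dNai, dCli, dm, dh, dn])

    return f_gnp
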