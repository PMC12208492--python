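"""Gating kinetics, voltage-gated currents, the Na+/K+ pump and stimuli.

Voltage-gated currents come in two interchangeable formats sharing the same
reduced Traub-Miles (RTM) m/h/n kinetics:

* the circuit (RTM) format  I_qV = -G_qM gate (V - E_q), and
* the GHK format            I'_qV = -F^2 P_qV / RT * gate * V * (...),

which differ in how the driving force depends on voltage and concentration.
A cubic normalisation factor f_q(V), fitted so that I'_qV / f_q(V) = I_qV at
steady-state concentrations, aligns the two at rest; once concentrations
drift the GHK format's conductance tracks the harmonic-mean concentration
while the circuit format's does not — that divergence is the entire point
of the v/kv/nav model variants.

Time is in ms throughout; rates are in 1/ms with V in mV, exactly as the
RTM rate functions are conventionally written.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .core_gnp import IonSpecies, ghk_current_density, harmonic_mean_concentration

__all__ = [
    "GateState",
    "PumpSpec",
    "StimulusProtocol",
    "FqFit",
    "rtm_rates",
    "gate_steady_state",
    "pump_current",
    "voltage_gated_currents_rtm",
    "voltage_gated_currents_ghk",
    "fit_fq",
    "eval_fq",
    "equivalent_max_conductance",
    "PRINTED_FQ_COEFFICIENTS",
]


@dataclass(frozen=True)
class GateState:
    """Hodgkin-Huxley activation/inactivation variables, each in [0, 1]."""

    m: float
    h: float
    n: float

    def __post_init__(self) -> None:
        for name in ("m", "h", "n"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"gate {name} = {p} outside [0, 1]")


def _lin_over_expm1(a: float, x: float, s: float) -> float:
    """a * x / (1 - exp(-x/s)) with the removable singularity at x = 0.

    This is the alpha_m / alpha_n shape; the limit at x = 0 is a*s.
    """
    if abs(x) < 1e-6:
        return a * s * (1.0 + x / (2.0 * s) + x * x / (12.0 * s * s))
    return a * x / (-math.expm1(-x / s))


def rtm_rates(v_mV: float) -> Tuple[float, float, float, float, float, float]:
    """Reduced Traub-Miles rate constants (am, bm, ah, bh, an, bn) in 1/ms.

    Singularities at V = -54 (alpha_m), V = -27 (beta_m) and V = -52
    (alpha_n) are removable and evaluated by series.
    """
    am = _lin_over_expm1(0.32, v_mV + 54.0, 4.0)
    bm = _lin_over_expm1(0.28, -(v_mV + 27.0), 5.0)  # 0.28 x /(e^{x/5}-1) = 0.28(-x)/(1-e^{x/5})
    ah = 0.128 * math.exp(-(v_mV + 50.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(v_mV + 27.0) / 5.0))
    an = _lin_over_expm1(0.032, v_mV + 52.0, 5.0)
    bn = 0.5 * math.exp(-(v_mV + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


def gate_steady_state(v_mV: float) -> GateState:
    """Steady-state gates p_inf = alpha / (alpha + beta)."""
    am, bm, ah, bh, an, bn = rtm_rates(v_mV)
    return GateState(am / (am + bm), ah / (ah + bh), an / (an + bn))


def gate_derivatives(v_mV: float, m: float, h: float, n: float) -> Tuple[float, float, float]:
    """dp/dt = alpha (1 - p) - beta p for p = m, h, n (1/ms)."""
    am, bm, ah, bh, an, bn = rtm_rates(v_mV)
    return (
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    )


@dataclass(frozen=True)
class PumpSpec:
    """Na+/K+-ATPase model: 3 Na+ out / 2 K+ in per cycle, electrogenic.

    mode="constant": the pump current is I_const (uA/cm^2, negative for the
    physiological direction).  mode="concentration_dependent": sigmoidal
    activation in [Na+]_i and [K+]_o with ceiling (vF/S) * M_NaK:

        I = -(vF/S) M_NaK / (1+e^{(25-[Na]i)/3}) / (1+e^{3.5-[K]o})
    """

    mode: str = "constant"
    I_const_uA_per_cm2: float = -1.16
    M_NaK_mM_per_s: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "concentration_dependent"):
            raise ValueError(f"unknown pump mode {self.mode!r}")
        if self.mode == "concentration_dependent" and self.M_NaK_mM_per_s <= 0:
            raise ValueError("M_NaK must be positive in concentration_dependent mode")

    def ceiling_uA_per_cm2(self, S_over_v: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Magnitude bound (vF/S) * M_NaK of the dependent-mode current."""
        return constants.F / S_over_v * self.M_NaK_mM_per_s * 100.0


def pump_current(
    Nai_mM: float,
    Ko_mM: float,
    spec: PumpSpec,
    S_over_v: float = 4.0e5,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Pump-induced current I_NaK in uA/cm^2 (negative = physiological)."""
    if spec.mode == "constant":
        return spec.I_const_uA_per_cm2
    if Nai_mM < 0 or Ko_mM < 0:
        raise ValueError("concentrations must be nonnegative")
    act_na = 1.0 / (1.0 + math.exp((25.0 - Nai_mM) / 3.0))
    act_k = 1.0 / (1.0 + math.exp(3.5 - Ko_mM))
    return -spec.ceiling_uA_per_cm2(S_over_v, constants) * act_na * act_k


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant glutamate open-probability schedule.

    ``intervals`` is a sequence of (t_start_ms, t_end_ms, po); outside every
    interval po = 0.  Intervals must not overlap and po must lie in [0, 1].
    """

    intervals: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        iv = tuple(tuple(map(float, i)) for i in self.intervals)
        for t0, t1, po in iv:
            if t1 <= t0:
                raise ValueError(f"empty stimulus interval [{t0}, {t1}]")
            if not 0.0 <= po <= 1.0:
                raise ValueError(f"po = {po} outside [0, 1]")
        for (a0, a1, _), (b0, b1, _) in zip(sorted(iv), sorted(iv)[1:]):
            if b0 < a1:
                raise ValueError("stimulus intervals overlap")
        object.__setattr__(self, "intervals", iv)

    @classmethod
    def step(cls, po: float, onset_ms: float = 0.0, offset_ms: float = math.inf) -> "StimulusProtocol":
        return cls(((onset_ms, offset_ms, po),))

    def po(self, t_ms: float) -> float:
        for t0, t1, po in self.intervals:
            if t0 <= t_ms < t1:
                return po
        return 0.0

    def change_points(self) -> List[float]:
        pts: List[float] = []
        for t0, t1, _ in self.intervals:
            pts.append(t0)
            if math.isfinite(t1):
                pts.append(t1)
        return sorted(set(pts))


def voltage_gated_currents_rtm(
    v_mV: float,
    gates: GateState,
    EK_mV: float,
    ENa_mV: float,
    GKM: float = 20.0,
    GNaM: float = 30.0,
) -> Tuple[float, float]:
    """Circuit-format gated currents (I_KV, I_NaV) in uA/cm^2.

    I_KV = -G_KM n^4 (V - E_K),  I_NaV = -G_NaM m^3 h (V - E_Na); maximal
    conductances in mS/cm^2.
    """
    IKV = -GKM * gates.n ** 4 * (v_mV - EK_mV)
    INaV = -GNaM * gates.m ** 3 * gates.h * (v_mV - ENa_mV)
    return IKV, INaV


def voltage_gated_currents_ghk(
    v_mV: float,
    gates: GateState,
    k_ion: IonSpecies,
    na_ion: IonSpecies,
    PKV: float = 1.70e-6,
    PNaV: float = 1.47e-6,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> Tuple[float, float]:
    """GHK-format gated currents (I'_KV, I'_NaV) in uA/cm^2.

    The gate factors multiply the full GHK current density of the ion at
    the given permeability.
    """
    IKp = gates.n ** 4 * ghk_current_density(PKV, k_ion, v_mV, constants)
    INap = gates.m ** 3 * gates.h * ghk_current_density(PNaV, na_ion, v_mV, constants)
    return IKp, INap


# --------------------------------------------------------------------------
# fq normalisation: cubic fit of the GHK/RTM current ratio at fixed
# (steady-state) concentrations.  The gate factors cancel in the ratio.
# --------------------------------------------------------------------------

#: published cubic coefficients [N3, N2, N1, N0] (V in mV), shipped as the
#: canonical inputs of the vGNP-family reproduction runs
PRINTED_FQ_COEFFICIENTS: Dict[str, Tuple[float, float, float, float]] = {
    "K": (-1.20e-7, 1.18e-5, 0.0075, 0.85),
    "Na": (9.41e-8, 4.64e-6, -0.0056, 1.11),
}


@dataclass(frozen=True)
class FqFit:
    """Cubic normalisation f_q(V) = N3 V^3 + N2 V^2 + N1 V + N0 (V in mV)."""

    coefficients: Tuple[float, float, float, float]
    ion_name: str = ""

    def __call__(self, v_mV: float) -> float:
        n3, n2, n1, n0 = self.coefficients
        return ((n3 * v_mV + n2) * v_mV + n1) * v_mV + n0


def eval_fq(fit: FqFit, v_mV: float) -> float:
    """Evaluate the cubic normalisation factor at V (no clamping)."""
    return fit(v_mV)


def fit_fq(
    ion: IonSpecies,
    P_ghk: float,
    G_max: float,
    v_range_mV: Tuple[float, float] = (-100.0, 50.0),
    step_mV: float = 1.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> FqFit:
    """Least-squares cubic fit of f_q(V) = I'_qV / I_qV at fixed concentrations.

    The ratio reduces to F^2 P c̄(V) / (RT G_max) (gates and driving-force
    zeros cancel analytically, so the ratio is smooth through V = E_q).
    Unweighted fit on a 1 mV grid over ``v_range_mV``.  Warns if the fitted
    cubic is nonpositive anywhere in the range, which would break the
    equivalent-conductance construction.
    """
    vs = np.arange(v_range_mV[0], v_range_mV[1] + 0.5 * step_mV, step_mV)
    ratio = np.array(
        [
            constants.F ** 2 * P_ghk * harmonic_mean_concentration(ion, v, constants)
            / (constants.RT * G_max * 10.0)  # G_max mS/cm^2 -> S/m^2
            for v in vs
        ]
    )
    coeffs = np.polyfit(vs, ratio, 3)
    fit = FqFit(tuple(coeffs), ion.name)
    if min(fit(v) for v in vs) <= 0.0:
        warnings.warn(
            f"fitted f_{ion.name}(V) is nonpositive inside the fitting range; "
            "the equivalent maximum conductance is undefined there",
            RuntimeWarning,
        )
    return fit


def equivalent_max_conductance(
    fit: FqFit,
    ion: IonSpecies,
    v_mV: float,
    P_ghk: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equivalent maximal conductance G'_qM = F^2 P c̄ / (RT f_q(V)), mS/cm^2.

    Reduces to the circuit-format maximal conductance at the concentrations
    and voltage the fit was made at, and tracks c̄ away from them.
    """
    fq = fit(v_mV)
    cbar = harmonic_mean_concentration(ion, v_mV, constants)
    return constants.F ** 2 * P_ghk * cbar / (constants.RT * fq) * 0.1
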