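"""Time integration, spike detection, firing-state classification and the
sliding-window current-difference analysis.

Integration uses a stiff-capable solver with tight tolerances
(rtol 1e-8, atol 1e-10 by default): the charge-voltage relation amplifies
concentration errors by ~1.2e4 mV/mM, so sloppy concentration tolerances
show up directly as millivolt-scale voltage noise.  The integration is
split at every stimulus change point so the solver never steps across a
discontinuity in po(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import DEFAULT_CONSTANTS
from .models import (
    GNP_FAMILY,
    ModelDefinition,
    make_rhs,
    membrane_voltage,
    state_names,
)

__all__ = [
    "SimResult",
    "FiringClassification",
    "run",
    "detect_spikes",
    "classify",
    "current_difference",
    "steady_state_initial",
]

SPIKE_THRESHOLD_MV = -20.0
SPIKE_REFRACTORY_MS = 2.0


# ---------------------------------------------------------------------------
# Vectorised current evaluation for stored trajectories
# ---------------------------------------------------------------------------

def _phi_vec(u: np.ndarray) -> np.ndarray:
    small = np.abs(u) < 1e-8
    u_safe = np.where(small, 1.0, u)
    out = u_safe / (-np.expm1(-u_safe))
    return np.where(small, 1.0 + u / 2.0 + u * u / 12.0, out)


def _ghk_vec(P: float, z: int, ci, co, V_mV: np.ndarray, vt_mV: float, F: float) -> np.ndarray:
    """Model-convention GHK current (uA/cm^2), vectorised over the trace."""
    u = z * np.asarray(V_mV) / vt_mV
    return -z * F * P * ((np.asarray(ci) - np.asarray(co)) * _phi_vec(u) + np.asarray(co) * u) * 100.0


def _poly3(c: Tuple[float, float, float, float], V: np.ndarray) -> np.ndarray:
    n3, n2, n1, n0 = c
    return ((n3 * V + n2) * V + n1) * V + n0


def _current_traces(defn: ModelDefinition, t_ms: np.ndarray, Y: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-family and per-ion current traces along a stored trajectory."""
    v = defn.variant
    cst, geom = defn.constants, defn.geometry
    vt, F = cst.vt_mV, cst.F
    names = state_names(v)
    s = {k: Y[i] for i, k in enumerate(names)}

    if v in ("chh", "fgnp"):
        ions = defn.reference_ions()
        Ki, Ko = np.full_like(t_ms, ions["K"].c_in), np.full_like(t_ms, ions["K"].c_out)
        Nai, Nao = np.full_like(t_ms, ions["Na"].c_in), np.full_like(t_ms, ions["Na"].c_out)
        Cli, Clo = np.full_like(t_ms, ions["Cl"].c_in), np.full_like(t_ms, ions["Cl"].c_out)
        V = s["V"]
    else:
        Ko, Nai, Cli = s["Ko"], s["Nai"], s["Cli"]
        Ki, Nao, Clo = defn.sigma["K"] - Ko, defn.sigma["Na"] - Nai, defn.sigma["Cl"] - Cli
        if v == "ihh":
            V = s["V"]
        else:
            V = np.array([membrane_voltage(defn, a, b, c) for a, b, c in zip(Ko, Nai, Cli)])

    EK = vt * np.log(Ko / Ki)
    ENa = vt * np.log(Nao / Nai)
    ECl = -vt * np.log(Clo / Cli)
    po = np.array([defn.stimulus.po(t) for t in t_ms])
    n4 = s["n"] ** 4
    m3h = s["m"] ** 3 * s["h"]

    from .models import glutamate_linearization, steady_state_leak_linearization

    if v in ("vgnp", "kvgnp"):
        IKV = n4 * _ghk_vec(defn.P_gated["K"], 1, Ki, Ko, V, vt, F) / _poly3(tuple(defn.fq_coefficients["K"]), V)
    else:
        IKV = -defn.GKM * n4 * (V - EK)
    if v in ("vgnp", "navgnp"):
        INaV = m3h * _ghk_vec(defn.P_gated["Na"], 1, Nai, Nao, V, vt, F) / _poly3(tuple(defn.fq_coefficients["Na"]), V)
    else:
        INaV = -defn.GNaM * m3h * (V - ENa)

    if v == "chh":
        GLH, ELH, _ = steady_state_leak_linearization(defn)
        IKL = np.zeros_like(V)
        INaL = np.zeros_like(V)
        IClL = np.zeros_like(V)
        IL = -GLH * (V - ELH)
    elif v == "ihh":
        _, _, Gl = steady_state_leak_linearization(defn)
        IKL = -Gl["K"] * (V - EK)
        INaL = -Gl["Na"] * (V - ENa)
        IClL = -Gl["Cl"] * (V - ECl)
        IL = IKL + INaL + IClL
    else:
        IKL = _ghk_vec(defn.P_leak["K"], 1, Ki, Ko, V, vt, F)
        INaL = _ghk_vec(defn.P_leak["Na"], 1, Nai, Nao, V, vt, F)
        IClL = _ghk_vec(defn.P_leak["Cl"], -1, Cli, Clo, V, vt, F)
        IL = IKL + INaL + IClL

    if v in ("chh", "fgnp"):
        Gglu, Eglu = glutamate_linearization(defn)
        IKG = np.zeros_like(V)
        INaG = np.zeros_like(V)
        IG = -po * Gglu * (V - Eglu)
    elif v == "ihh":
        gg = defn.gg_ihh()
        IKG = -po * gg["K"] * (V - EK)
        INaG = -po * gg["Na"] * (V - ENa)
        IG = IKG + INaG
    else:
        IKG = po * _ghk_vec(defn.P_glu["K"], 1, Ki, Ko, V, vt, F)
        INaG = po * _ghk_vec(defn.P_glu["Na"], 1, Nai, Nao, V, vt, F)
        IG = IKG + INaG

    if defn.pump.mode == "constant":
        INaK = np.full_like(V, defn.pump.I_const_uA_per_cm2)
    else:
        ceiling = defn.pump.ceiling_uA_per_cm2(geom.S_over_v, cst)
        INaK = -ceiling / (1.0 + np.exp((25.0 - Nai) / 3.0)) / (1.0 + np.exp(3.5 - Ko))

    IV = IKV + INaV
    return {
        "V_mV": V, "po": po,
        "IKV": IKV, "INaV": INaV, "IKL": IKL, "INaL": INaL, "IClL": IClL,
        "IKG": IKG, "INaG": INaG, "INaK": INaK,
        "IV": IV, "IL": IL, "IG": IG, "Idiff": IV + IL + IG,
        "EK": EK, "ENa": ENa, "ECl": ECl,
    }


@dataclass
class SimResult:
    """A simulated trajectory with its current decomposition.

    ``states`` maps each dynamic variable name to its trace; ``V_mV`` is
    always present (recomputed from charge for the GNP family).  Current
    traces are in uA/cm^2, depolarizing-positive, and satisfy
    Idiff = IV + IL + IG at every sample.
    """

    definition: ModelDefinition
    t_ms: np.ndarray
    states: Dict[str, np.ndarray]
    currents: Dict[str, np.ndarray]
    spike_times_ms: np.ndarray

    @property
    def V_mV(self) -> np.ndarray:
        return self.currents["V_mV"]

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t_ms}
        cols.update({k: v for k, v in self.states.items()})
        if "V" not in self.states:
            cols["V"] = self.V_mV
        for key in ("IV", "IL", "IG", "INaK", "Idiff", "IKV", "INaV", "IKL", "INaL", "IClL", "IKG", "INaG", "EK", "ENa", "ECl", "po"):
            cols[key] = self.currents[key]
        return pd.DataFrame(cols)

    def concentration_deviations(self, reference: Optional[Dict[str, float]] = None) -> Dict[str, np.ndarray]:
        """|Delta [q]| traces of the dynamic concentrations vs a reference."""
        if reference is None:
            reference = {k: self.states[k][0] for k in ("Ko", "Nai", "Cli") if k in self.states}
        return {k: np.abs(self.states[k] - reference[k]) for k in reference}


@dataclass(frozen=True)
class FiringClassification:
    """Firing-state label with the evidence it was based on."""

    label: str  # resting | phasic_spiking | tonic_spiking | depolarization_block
    spike_times_ms: np.ndarray
    mean_frequency_Hz: float


def detect_spikes(
    V_mV: np.ndarray,
    t_ms: np.ndarray,
    threshold_mV: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = SPIKE_REFRACTORY_MS,
) -> np.ndarray:
    """Upward threshold crossings with a refractory separation, in ms.

    Crossing times are linearly interpolated between samples.
    """
    V = np.asarray(V_mV, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    if V.shape != t.shape:
        raise ValueError("V and t must have matching shapes")
    above = V >= threshold_mV
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -math.inf
    for i in idx:
        frac = (threshold_mV - V[i]) / (V[i + 1] - V[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory_ms:
            times.append(tc)
            last = tc
    return np.array(times)


def run(
    defn: ModelDefinition,
    y0: Sequence[float],
    t_span_ms: Tuple[float, float],
    sample_dt_ms: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_step_ms: float = math.inf,
) -> SimResult:
    """Integrate a model variant and return the sampled trajectory.

    The span is integrated piecewise between stimulus change points.  A
    solver failure raises RuntimeError naming the failing time and state.
    """
    t0, t1 = map(float, t_span_ms)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    f = make_rhs(defn)
    cuts = [t for t in defn.stimulus.change_points() if t0 < t < t1]
    edges = [t0] + cuts + [t1]
    ts: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    nseg = len(edges) - 1
    for k in range(nseg):
        a, b = edges[k], edges[k + 1]
        t_eval = np.arange(a, b, sample_dt_ms)
        if t_eval.size == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(
            f, (a, b), y, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
            max_step=max_step_ms,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t = {sol.t[-1] if sol.t.size else a} ms, "
                f"state = {sol.y[:, -1] if sol.t.size else y}: {sol.message}"
            )
        y = sol.y[:, -1]
        keep = slice(0, -1) if k < nseg - 1 else slice(None)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    states = dict(zip(state_names(defn.variant), Y))
    cur = _current_traces(defn, t, Y)
    spikes = detect_spikes(cur["V_mV"], t)
    return SimResult(defn, t, states, cur, spikes)


# -- classification ---------------------------------------------------------

#: configurable classification thresholds
CLASSIFY_DEFAULTS = dict(
    rest_band_mV=10.0,
    tonic_cv_max=0.5,
    db_quiet_ms=500.0,
    db_mean_v_mV=-45.0,
)


def classify(
    sim: SimResult,
    window_ms: Optional[Tuple[float, float]] = None,
    **overrides: float,
) -> FiringClassification:
    """Classify the firing state within a window.

    Decision rules (thresholds overridable):

    * depolarization_block: no spikes in the final ``db_quiet_ms`` and the
      mean voltage there stays above ``db_mean_v_mV``;
    * resting: no spikes and the end voltage within ``rest_band_mV`` of the
      window-start voltage;
    * tonic_spiking: ISI coefficient of variation < ``tonic_cv_max`` with
      spiking persisting to the window end;
    * phasic_spiking: spikes confined to the first half, resting after.
    """
    p = dict(CLASSIFY_DEFAULTS, **overrides)
    t = sim.t_ms
    if window_ms is None:
        window_ms = (t[0], t[-1])
    w0, w1 = window_ms
    if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
        raise ValueError("classification window outside the simulated span")
    if w1 - w0 < 2 * p["db_quiet_ms"]:
        raise ValueError("classification window too short")
    mask = (t >= w0) & (t <= w1)
    V = sim.V_mV[mask]
    tw = t[mask]
    spikes = sim.spike_times_ms[(sim.spike_times_ms >= w0) & (sim.spike_times_ms <= w1)]
    n = spikes.size
    freq = n / ((w1 - w0) / 1000.0)

    tail = tw >= w1 - p["db_quiet_ms"]
    tail_spikes = spikes[spikes >= w1 - p["db_quiet_ms"]]
    if tail_spikes.size == 0 and np.mean(V[tail]) > p["db_mean_v_mV"]:
        return FiringClassification("depolarization_block", spikes, freq)
    if n == 0:
        if abs(V[-1] - V[0]) <= p["rest_band_mV"]:
            return FiringClassification("resting", spikes, freq)
        return FiringClassification("phasic_spiking", spikes, freq)  # drifting, no spikes
    if n >= 3:
        isi = np.diff(spikes)
        cv = np.std(isi) / np.mean(isi)
        spiking_to_end = (w1 - spikes[-1]) < max(2.0 * np.mean(isi), p["db_quiet_ms"])
        if cv < p["tonic_cv_max"] and spiking_to_end:
            return FiringClassification("tonic_spiking", spikes, freq)
    if spikes[-1] <= w0 + 0.5 * (w1 - w0):
        return FiringClassification("phasic_spiking", spikes, freq)
    return FiringClassification("tonic_spiking", spikes, freq)


def current_difference(
    sim_a: SimResult,
    sim_b: SimResult,
    window_s: float = 8.0,
    step_s: float = 4.0,
) -> pd.DataFrame:
    """Sliding-window averaged per-ion electrodiffusive current differences.

    For each ion the instantaneous difference between models a and b is
    reconstructed from the stored concentration balance (model derivative
    evaluations, not finite differences of the sampled traces):

        dI_K  = -(v/S) F (d[K]o/dt|_a - d[K]o/dt|_b) + 2 (INaK_a - INaK_b)
        dI_Na = +(v/S) F (d[Na]i/dt|_a - d[Na]i/dt|_b) - 3 (INaK_a - INaK_b)
        dI_Cl = -(v/S) F (d[Cl]i/dt|_a - d[Cl]i/dt|_b)

    which equals the difference of the summed passive currents of each ion.
    Both runs must share the stimulus and time grid.  Returns a frame with
    window centers (s) and dI_K, dI_Na, dI_Cl, dI_diff (uA/cm^2).
    """
    if sim_a.t_ms.shape != sim_b.t_ms.shape or not np.allclose(sim_a.t_ms, sim_b.t_ms):
        raise ValueError("simulations must share the time grid")
    if sim_a.definition.stimulus != sim_b.definition.stimulus:
        raise ValueError("simulations must share the stimulus protocol")

    def passive(sim: SimResult) -> Dict[str, np.ndarray]:
        c = sim.currents
        return {
            "K": c["IKV"] + c["IKL"] + c["IKG"],
            "Na": c["INaV"] + c["INaL"] + c["INaG"],
            "Cl": c["IClL"],
        }

    pa, pb = passive(sim_a), passive(sim_b)
    t_s = sim_a.t_ms / 1000.0
    d = {q: pa[q] - pb[q] for q in ("K", "Na", "Cl")}
    centers, rows = [], []
    half = window_s / 2.0
    t_end = t_s[-1]
    c = t_s[0] + half
    while c + half <= t_end + 1e-9:
        m = (t_s >= c - half) & (t_s <= c + half)
        row = {f"dI_{q}": float(np.mean(d[q][m])) for q in ("K", "Na", "Cl")}
        row["dI_diff"] = row["dI_K"] + row["dI_Na"] + row["dI_Cl"]
        row["t_center_s"] = c
        rows.append(row)
        c += step_s
    return pd.DataFrame(rows, columns=["t_center_s", "dI_K", "dI_Na", "dI_Cl", "dI_diff"])


def steady_state_initial(defn: ModelDefinition) -> np.ndarray:
    """The variant's resting fixed point (po = 0) as an initial state vector.

    Because the charge relation amplifies mM-scale rounding into tens of
    millivolts, initial conditions must be the *solved* fixed point, not
    the rounded reference concentrations.
    """
    from .bifurcation import find_fixed_point  # local import to avoid a cycle

    fp = find_fixed_point(defn)
    return fp.state_vector
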