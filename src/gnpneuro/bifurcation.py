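"""Fixed points, branch continuation over the pump current, and stability.

The continuation parameter is the (constant) Na+/K+-ATPase current INaK.
Fixed points are solved with the gate variables eliminated at their
voltage-dependent steady state (the gate equations are strictly stable, so
this loses no roots); stability is then judged from the eigenvalues of the
full-state Jacobian, because Hopf frequencies involve the gate dynamics.

For the GNP family the root system is parametrised as (V, [K+]o, [Na+]i)
with [Cl-]i eliminated through the charge relation — solving directly in
concentration space is hopeless because V moves ~1.2e4 mV per mM of net
charge.  For iHH the unknowns are (V, [K+]o, [Na+]i, [Cl-]i).

Branches are flagged unphysical wherever a complemented concentration goes
negative (the GNP-family GHK currents remain evaluable there, which is
exactly why those branches exist mathematically but are split for
reporting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .gating_pumps import PumpSpec, StimulusProtocol, gate_steady_state
from .models import (
    GNP_FAMILY,
    ModelDefinition,
    complement_concentrations,
    make_rhs,
    membrane_voltage,
    state_names,
)

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "find_fixed_point",
    "continue_branch",
    "detect_bifurcations",
    "seed_db_state",
    "hopf_point",
]

RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A converged equilibrium of one model variant."""

    variant: str
    INaK_uA_per_cm2: Optional[float]  # None when the pump is concentration-dependent
    state: Dict[str, float]  # named state incl. V
    state_vector: np.ndarray  # flat vector in the variant's layout
    eigenvalues: np.ndarray  # full-system Jacobian eigenvalues (1/ms)
    residual: float
    physical: bool

    @property
    def V_mV(self) -> float:
        return self.state["V"]

    #: eigenvalues smaller than this (1/ms) are treated as neutral: the iHH
    #: variant conserves V - V_charge exactly, contributing an exact zero
    #: mode that finite differencing turns into numerical dust
    NEUTRAL_TOL = 1e-7

    @property
    def stable(self) -> bool:
        return bool(self.max_re_eig < self.NEUTRAL_TOL)

    @property
    def max_re_eig(self) -> float:
        keep = np.abs(self.eigenvalues) >= self.NEUTRAL_TOL
        return float(np.max(self.eigenvalues.real[keep])) if keep.any() else 0.0

    @property
    def leading_complex_re(self) -> float:
        """Largest real part among complex-conjugate eigenvalue pairs."""
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > 1e-12]
        return float(np.max(cplx.real)) if cplx.size else -math.inf

    @property
    def leading_real_eig(self) -> float:
        """Largest purely real eigenvalue (neutral modes excluded)."""
        mask = (np.abs(self.eigenvalues.imag) <= 1e-12) & (np.abs(self.eigenvalues) >= self.NEUTRAL_TOL)
        re = self.eigenvalues[mask]
        return float(np.max(re.real)) if re.size else -math.inf


@dataclass
class BifurcationDiagram:
    """Fixed-point branch(es) with detected SN/HB markers."""

    variant: str
    points: List[FixedPoint] = field(default_factory=list)
    sn_points: List[FixedPoint] = field(default_factory=list)
    hb_points: List[FixedPoint] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        markers = {id(p): "SN" for p in self.sn_points}
        markers.update({id(p): "HB" for p in self.hb_points})
        for p in self.points:
            rows.append(
                {
                    "INaK": p.INaK_uA_per_cm2,
                    "V": p.state["V"],
                    "Ko": p.state.get("Ko", math.nan),
                    "Nai": p.state.get("Nai", math.nan),
                    "Cli": p.state.get("Cli", math.nan),
                    "max_re_eig": p.max_re_eig,
                    "stable": p.stable,
                    "physical": p.physical,
                    "point_type": markers.get(id(p), ""),
                }
            )
        for p in self.sn_points + self.hb_points:
            if id(p) not in {id(q) for q in self.points}:
                rows.append(
                    {
                        "INaK": p.INaK_uA_per_cm2, "V": p.state["V"],
                        "Ko": p.state.get("Ko", math.nan), "Nai": p.state.get("Nai", math.nan),
                        "Cli": p.state.get("Cli", math.nan), "max_re_eig": p.max_re_eig,
                        "stable": p.stable, "physical": p.physical,
                        "point_type": "SN" if any(id(p) == id(q) for q in self.sn_points) else "HB",
                    }
                )
        return pd.DataFrame(rows).sort_values("INaK").reset_index(drop=True)


def _constant_pump(defn: ModelDefinition, INaK: Optional[float]) -> ModelDefinition:
    if INaK is None:
        return defn
    return defn.with_(pump=PumpSpec(mode="constant", I_const_uA_per_cm2=float(INaK)))


def _quiet(defn: ModelDefinition) -> ModelDefinition:
    if defn.stimulus.intervals:
        return defn.with_(stimulus=StimulusProtocol())
    return defn


def _full_state(defn: ModelDefinition, V: float, Ko: float, Nai: float, Cli: float) -> np.ndarray:
    g = gate_steady_state(V)
    vals = {"V": V, "Ko": Ko, "Nai": Nai, "Cli": Cli, "m": g.m, "h": g.h, "n": g.n}
    return np.array([vals[k] for k in state_names(defn.variant)])


def _cli_from_charge(defn: ModelDefinition, V: float, Ko: float, Nai: float) -> float:
    geom, cst = defn.geometry, defn.constants
    vcoef = cst.F / (2.0 * geom.S_over_v * geom.Cm_F_per_m2) * 1000.0
    s = defn.sigma
    return 0.5 * (s["K"] - s["Na"] + s["Cl"] - geom.A_in_mM - 2.0 * Ko + 2.0 * Nai - V / vcoef)


def full_jacobian(defn: ModelDefinition, y: np.ndarray, t_ms: float = 0.0) -> np.ndarray:
    """Central finite-difference Jacobian of the full dynamic system (1/ms).

    Per-variable steps are 1e-6 of the variable's characteristic scale
    (1 mM for concentrations, 1 mV for V, 1 for gates).
    """
    f = make_rhs(defn)
    n = y.size
    J = np.empty((n, n))
    h = 1e-6
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (f(t_ms, y + e) - f(t_ms, y - e)) / (2.0 * h)
    return J


def find_fixed_point(
    defn: ModelDefinition,
    INaK_uA_per_cm2: Optional[float] = None,
    guess: Optional[Dict[str, float]] = None,
    tol: float = 1e-12,
) -> FixedPoint:
    """Solve for an equilibrium with gates at steady state, stimulus off.

    ``INaK_uA_per_cm2`` overrides the pump with a constant current (the
    continuation parameter); with None the definition's own pump is used.
    ``guess`` may give V/Ko/Nai/Cli starting values (defaults: reference
    state).  Raises RuntimeError with the residual on non-convergence.
    """
    defn = _quiet(_constant_pump(defn, INaK_uA_per_cm2))
    f = make_rhs(defn)
    ref = dict(defn.reference_state)
    if guess:
        ref.update(guess)
    variant = defn.variant

    def _guarded(fn):
        # root solvers probe states outside the model's domain (negative
        # complements under a log); answer with a smooth penalty instead of
        # crashing so the solver can retreat
        def wrapped(x):
            try:
                return fn(x)
            except (ValueError, OverflowError):
                return np.full(len(x), 1e6) * (1.0 + np.abs(x))
        return wrapped

    if variant in GNP_FAMILY:
        @_guarded
        def resid(x):
            V, Ko, Nai = x
            Cli = _cli_from_charge(defn, V, Ko, Nai)
            y = _full_state(defn, V, Ko, Nai, Cli)
            return f(0.0, y)[:3] * 1e3  # mM/s scale

        x0 = [ref["V"], ref["Ko"], ref["Nai"]]
        sol = root(resid, x0, method="hybr", tol=tol)
        V, Ko, Nai = sol.x
        Cli = _cli_from_charge(defn, V, Ko, Nai)
    elif variant == "ihh":
        # iHH conserves V - V_charge along trajectories, so the naive
        # (V, Ko, Nai, Cli) system is rank-deficient: fixed points form a
        # one-parameter family.  Trajectories started from charge-consistent
        # states stay on the V = V_charge leaf, so that relation replaces
        # the (automatically satisfied) dV/dt = 0 equation.
        @_guarded
        def resid(x):
            V, Ko, Nai = x
            Cli = _cli_from_charge(defn, V, Ko, Nai)
            y = _full_state(defn, V, Ko, Nai, Cli)
            return f(0.0, y)[1:4] * 1e3

        x0 = [ref["V"], ref["Ko"], ref["Nai"]]
        sol = root(resid, x0, method="hybr", tol=tol)
        V, Ko, Nai = sol.x
        Cli = _cli_from_charge(defn, V, Ko, Nai)
    elif variant in ("chh", "fgnp"):
        @_guarded
        def resid(x):
            y = _full_state(defn, x[0], ref["Ko"], ref["Nai"], ref["Cli"])
            return f(0.0, y)[:1]

        sol = root(resid, [ref["V"]], method="hybr", tol=tol)
        V = float(sol.x[0])
        Ko, Nai, Cli = ref["Ko"], ref["Nai"], ref["Cli"]
    else:  # pragma: no cover
        raise ValueError(f"unsupported variant {variant!r}")

    y = _full_state(defn, V, Ko, Nai, Cli)
    res = float(np.max(np.abs(f(0.0, y))))
    if res > 1e-6:  # accept on residual; hybr can report no-progress at the root
        raise RuntimeError(f"fixed point did not converge (residual {res:.3e}): {sol.message}")
    J = full_jacobian(defn, y)
    eig = np.linalg.eigvals(J)
    conc = complement_concentrations(Ko, Nai, Cli, defn.sigma)
    physical = all(v >= 0.0 for v in conc.values())
    g = gate_steady_state(V)
    state = {"V": V, "Ko": Ko, "Nai": Nai, "Cli": Cli, "m": g.m, "h": g.h, "n": g.n}
    return FixedPoint(variant, INaK_uA_per_cm2, state, y, eig, res, physical)


def seed_db_state(
    defn: ModelDefinition,
    INaK_uA_per_cm2: float,
    po_pulse: float = 0.83,
    pulse_ms: float = 35000.0,
    relax_ms: float = 10000.0,
) -> Dict[str, float]:
    """Drive the neuron into depolarization block and relax onto the DB
    equilibrium: a strong glutamate pulse followed by quiet integration
    under the given constant pump current.  Returns a fixed-point guess.
    """
    # Pulse under the concentration-dependent pump from the physiological
    # rest: with a strong constant pump there is no physical resting state
    # and the stimulus cannot win against the pump, so depolarization block
    # is never entered.  Only the relaxation runs under the constant
    # continuation pump (the DB state is stable there).
    pump_dep = PumpSpec(mode="concentration_dependent", M_NaK_mM_per_s=0.70)
    rest_defn = _quiet(defn.with_(pump=PumpSpec(mode="concentration_dependent", M_NaK_mM_per_s=0.3)))
    fp0 = find_fixed_point(rest_defn)
    pulsed = defn.with_(pump=pump_dep, stimulus=StimulusProtocol.step(po_pulse, 0.0, pulse_ms))
    f = make_rhs(pulsed)
    sol = solve_ivp(f, (0.0, pulse_ms), fp0.state_vector, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"DB seeding pulse failed: {sol.message}")
    quiet = _quiet(_constant_pump(defn, INaK_uA_per_cm2))
    f2 = make_rhs(quiet)
    sol2 = solve_ivp(f2, (0.0, relax_ms), sol.y[:, -1], method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol2.success:
        raise RuntimeError(f"DB relaxation failed: {sol2.message}")
    s = dict(zip(state_names(defn.variant), sol2.y[:, -1]))
    if "V" not in s:
        s["V"] = membrane_voltage(defn, s["Ko"], s["Nai"], s["Cli"])
    return {k: s[k] for k in ("V", "Ko", "Nai", "Cli")}


def continue_branch(
    defn: ModelDefinition,
    inak_start: float,
    inak_stop: float,
    seed_guess: Optional[Dict[str, float]] = None,
    step: float = 0.05,
    min_step: float = 1e-4,
    max_step: float = 0.2,
) -> BifurcationDiagram:
    """Natural-parameter continuation of a fixed-point branch over INaK.

    Adaptive stepping with warm starts: the step shrinks on solver failure
    or fast state movement and grows back on easy stretches; the branch
    terminates (with the reason recorded on the diagram) if the step
    collapses below ``min_step``.  Unphysical points (negative complement
    concentrations) are kept and flagged, so callers can split branches.
    """
    diagram = BifurcationDiagram(defn.variant)
    direction = 1.0 if inak_stop >= inak_start else -1.0
    inak = inak_start
    guess = dict(seed_guess) if seed_guess else None
    fp = find_fixed_point(defn, inak, guess)
    diagram.points.append(fp)
    h = step
    while (inak_stop - inak) * direction > 1e-12:
        h_try = min(h, abs(inak_stop - inak))
        nxt = inak + direction * h_try
        prev = diagram.points[-1]
        g = {k: prev.state[k] for k in ("V", "Ko", "Nai", "Cli")}
        try:
            fp = find_fixed_point(defn, nxt, g)
            moved = abs(fp.state["V"] - prev.state["V"])
            if moved > 5.0 and h_try > min_step:
                h = max(min_step, h_try / 4.0)
                continue
        except RuntimeError:
            if h_try <= min_step:
                break  # branch terminated: step collapse
            h = max(min_step, h_try / 4.0)
            continue
        diagram.points.append(fp)
        inak = nxt
        h = min(max_step, h_try * 1.5)
    return diagram


def _bisect_crossing(
    defn: ModelDefinition,
    lo: FixedPoint,
    hi: FixedPoint,
    key: Callable[[FixedPoint], float],
    tol_inak: float = 0.005,
) -> FixedPoint:
    a, fa = lo, key(lo)
    b, fb = hi, key(hi)
    while abs(b.INaK_uA_per_cm2 - a.INaK_uA_per_cm2) > tol_inak:
        mid_inak = 0.5 * (a.INaK_uA_per_cm2 + b.INaK_uA_per_cm2)
        g = {k: 0.5 * (a.state[k] + b.state[k]) for k in ("V", "Ko", "Nai", "Cli")}
        mid = find_fixed_point(defn, mid_inak, g)
        fm = key(mid)
        if (fa < 0) == (fm < 0):
            a, fa = mid, fm
        else:
            b, fb = mid, fm
    return a if abs(fa) < abs(fb) else b


def detect_bifurcations(defn: ModelDefinition, diagram: BifurcationDiagram, tol_inak: float = 0.005) -> BifurcationDiagram:
    """Locate saddle-node and Hopf points along a continued branch.

    SN: a purely real eigenvalue crosses zero between consecutive branch
    points; HB: the real part of the leading complex-conjugate pair does.
    Each crossing is sharpened by bisection in INaK to ``tol_inak``.
    """
    pts = diagram.points
    for a, b in zip(pts, pts[1:]):
        ra, rb = a.leading_real_eig, b.leading_real_eig
        if math.isfinite(ra) and math.isfinite(rb) and (ra < 0) != (rb < 0):
            diagram.sn_points.append(_bisect_crossing(defn, a, b, lambda p: p.leading_real_eig, tol_inak))
        ca, cb = a.leading_complex_re, b.leading_complex_re
        if math.isfinite(ca) and math.isfinite(cb) and (ca < 0) != (cb < 0):
            diagram.hb_points.append(_bisect_crossing(defn, a, b, lambda p: p.leading_complex_re, tol_inak))
    return diagram


def hopf_point(
    defn: ModelDefinition,
    inak_start: float = -10.0,
    inak_stop: float = -20.0,
    seed: Optional[Dict[str, float]] = None,
    step: float = 0.1,
    tol_inak: float = 0.005,
) -> FixedPoint:
    """Continue the depolarization-block branch over INaK and return the
    Hopf point where it loses stability.

    The DB branch is seeded by driving the model into depolarization block
    (strong glutamate pulse, then relaxation) at ``inak_start`` unless an
    explicit seed guess is given.
    """
    if seed is None:
        seed = seed_db_state(defn, inak_start)
    diagram = continue_branch(defn, inak_start, inak_stop, seed, step=step)
    detect_bifurcations(defn, diagram, tol_inak)
    if not diagram.hb_points:
        raise RuntimeError(
            f"no Hopf point found on the DB branch of {defn.variant} in "
            f"[{inak_start}, {inak_stop}] uA/cm^2"
        )
    # the DB-relevant HB is the one at the largest |INaK|
    return max(diagram.hb_points, key=lambda p: abs(p.INaK_uA_per_cm2))
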