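"""Configuration parsing, the canonical parameter registry and result writers.

The config is YAML with units spelled in the key names (``Cm_uF_per_cm2``,
``P_leak_m_per_s`` ...): unit mistakes are the dominant failure mode in
electrodiffusion models, where 1 A/m^2 is 100 uA/cm^2.  Unknown keys are
rejected, every physical value is range-checked, and an empty file yields
the full canonical default configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .channels import (
    LEAK_DENSITY_PER_CM2,
    LEAK_SINGLE_CHANNEL_P,
    AMPA_DENSITY_PER_CM2,
    P_CA_GLUR2LESS,
    PHYSIOLOGICAL,
    PORE_DIAMETER_M,
    ampa_channel,
    gabaa_channel,
)
from .constants import PhysicalConstants
from .core_gnp import MembraneGeometry
from .gating_pumps import PRINTED_FQ_COEFFICIENTS, PumpSpec, StimulusProtocol
from .models import (
    DEFAULT_P_GATED,
    DEFAULT_P_GLU,
    DEFAULT_P_LEAK,
    DEFAULT_REFERENCE,
    DEFAULT_SIGMA,
    PRINTED_GG_IHH,
    VARIANTS,
    ModelDefinition,
)

__all__ = ["RunConfig", "load_config", "write_results", "fixtures"]

_TOP_KEYS = {
    "model", "T_K", "Cm_uF_per_cm2", "S_over_v_per_m", "A_in_mM",
    "sigma_mM", "P_leak_m_per_s", "P_glu_m_per_s", "P_gated_m_per_s",
    "GKM_mS_per_cm2", "GNaM_mS_per_cm2", "GG_iHH_mS_per_cm2",
    "pump", "stimulus_ms", "fq_coefficients", "reference_state",
    "solver", "seed",
}
_PUMP_KEYS = {"mode", "I_const_uA_per_cm2", "M_NaK_mM_per_s"}
_SOLVER_KEYS = {"rtol", "atol", "sample_dt_ms", "method", "tmax_ms"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration with canonical defaults filled."""

    model: str = "gnp"
    constants: PhysicalConstants = PhysicalConstants()
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
    solver: Mapping[str, Any] = field(
        default_factory=lambda: dict(rtol=1e-8, atol=1e-10, sample_dt_ms=0.25, method="LSODA", tmax_ms=1000.0)
    )
    seed: int = 0  # reserved; all current computations are deterministic

    def definition(self) -> ModelDefinition:
        return ModelDefinition(
            variant=self.model,
            constants=self.constants,
            geometry=self.geometry,
            sigma=dict(self.sigma),
            P_leak=dict(self.P_leak),
            P_glu=dict(self.P_glu),
            P_gated=dict(self.P_gated),
            GKM=self.GKM,
            GNaM=self.GNaM,
            GG_iHH=dict(self.GG_iHH) if self.GG_iHH is not None else None,
            pump=self.pump,
            stimulus=self.stimulus,
            fq_coefficients=dict(self.fq_coefficients),
            reference_state=dict(self.reference_state),
        )

    def resolved(self) -> Dict[str, Any]:
        """The full resolved parameter set as plain JSON-serialisable data."""
        return {
            "model": self.model,
            "T_K": self.constants.T,
            "F_C_per_mol": self.constants.F,
            "R_J_per_mol_K": self.constants.R,
            "Cm_uF_per_cm2": self.geometry.Cm_uF_per_cm2,
            "S_over_v_per_m": self.geometry.S_over_v,
            "A_in_mM": self.geometry.A_in_mM,
            "sigma_mM": dict(self.sigma),
            "P_leak_m_per_s": dict(self.P_leak),
            "P_glu_m_per_s": dict(self.P_glu),
            "P_gated_m_per_s": dict(self.P_gated),
            "GKM_mS_per_cm2": self.GKM,
            "GNaM_mS_per_cm2": self.GNaM,
            "GG_iHH_mS_per_cm2": dict(self.GG_iHH) if self.GG_iHH else None,
            "pump": {
                "mode": self.pump.mode,
                "I_const_uA_per_cm2": self.pump.I_const_uA_per_cm2,
                "M_NaK_mM_per_s": self.pump.M_NaK_mM_per_s,
            },
            "stimulus_ms": [list(i) for i in self.stimulus.intervals],
            "fq_coefficients": {k: list(v) for k, v in self.fq_coefficients.items()},
            "reference_state": dict(self.reference_state),
            "solver": dict(self.solver),
            "seed": self.seed,
        }


def _check_keys(given: Mapping, allowed: set, context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}; allowed: {sorted(allowed)}")


def _ion_map(raw: Mapping, ions: Sequence[str], context: str, positive: bool = True) -> Dict[str, float]:
    _check_keys(raw, set(ions), context)
    out = {}
    for k in ions:
        if k in raw:
            v = float(raw[k])
            if positive and v < 0:
                raise ValueError(f"{context}.{k} must be nonnegative (got {v})")
            out[k] = v
    return out


def load_config(path: Optional[str | Path] = None, data: Optional[Mapping] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or absent) file produces the full default configuration.
    Schema violations raise ValueError naming the offending key and the
    expected unit.
    """
    if data is None:
        raw = {}
        if path is not None:
            text = Path(path).read_text()
            raw = yaml.safe_load(text) or {}
    else:
        raw = dict(data)
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    model = str(raw.get("model", "gnp")).lower()
    if model not in VARIANTS:
        raise ValueError(f"model must be one of {VARIANTS}, got {model!r}")

    constants = PhysicalConstants(T=float(raw.get("T_K", 309.15)))
    geometry = MembraneGeometry(
        Cm_uF_per_cm2=float(raw.get("Cm_uF_per_cm2", 1.0)),
        S_over_v=float(raw.get("S_over_v_per_m", 4.0e5)),
        A_in_mM=float(raw.get("A_in_mM", 110.0)),
    )
    sigma = dict(DEFAULT_SIGMA, **_ion_map(raw.get("sigma_mM", {}), ("K", "Na", "Cl"), "sigma_mM"))
    P_leak = dict(DEFAULT_P_LEAK, **_ion_map(raw.get("P_leak_m_per_s", {}), ("K", "Na", "Cl"), "P_leak_m_per_s"))
    P_glu = dict(DEFAULT_P_GLU, **_ion_map(raw.get("P_glu_m_per_s", {}), ("K", "Na"), "P_glu_m_per_s"))
    P_gated = dict(DEFAULT_P_GATED, **_ion_map(raw.get("P_gated_m_per_s", {}), ("K", "Na"), "P_gated_m_per_s"))

    GG = raw.get("GG_iHH_mS_per_cm2")
    GG_iHH = _ion_map(GG, ("K", "Na"), "GG_iHH_mS_per_cm2") if GG is not None else None

    pump_raw = raw.get("pump", {})
    _check_keys(pump_raw, _PUMP_KEYS, "pump")
    pump = PumpSpec(
        mode=pump_raw.get("mode", "constant"),
        I_const_uA_per_cm2=float(pump_raw.get("I_const_uA_per_cm2", -1.16)),
        M_NaK_mM_per_s=float(pump_raw.get("M_NaK_mM_per_s", 0.3)),
    )

    stim_raw = raw.get("stimulus_ms", [])
    stimulus = StimulusProtocol(tuple(tuple(map(float, iv)) for iv in stim_raw))

    fq = dict(PRINTED_FQ_COEFFICIENTS)
    for k, v in (raw.get("fq_coefficients") or {}).items():
        if k not in ("K", "Na"):
            raise ValueError(f"fq_coefficients keys must be K/Na, got {k!r}")
        if len(v) != 4:
            raise ValueError(f"fq_coefficients.{k} must have 4 entries [N3,N2,N1,N0]")
        fq[k] = tuple(map(float, v))

    ref = dict(DEFAULT_REFERENCE)
    ref_raw = raw.get("reference_state", {})
    _check_keys(ref_raw, {"Ko", "Nai", "Cli", "V"}, "reference_state")
    ref.update({k: float(v) for k, v in ref_raw.items()})

    solver = dict(rtol=1e-8, atol=1e-10, sample_dt_ms=0.25, method="LSODA", tmax_ms=1000.0)
    sol_raw = raw.get("solver", {})
    _check_keys(sol_raw, _SOLVER_KEYS, "solver")
    solver.update(sol_raw)
    for k in ("rtol", "atol", "sample_dt_ms", "tmax_ms"):
        solver[k] = float(solver[k])
        if solver[k] <= 0:
            raise ValueError(f"solver.{k} must be positive")

    gkm = float(raw.get("GKM_mS_per_cm2", 20.0))
    gnam = float(raw.get("GNaM_mS_per_cm2", 30.0))
    if gkm < 0 or gnam < 0:
        raise ValueError("maximal conductances must be nonnegative (mS/cm2)")

    return RunConfig(
        model=model, constants=constants, geometry=geometry, sigma=sigma,
        P_leak=P_leak, P_glu=P_glu, P_gated=P_gated, GKM=gkm, GNaM=gnam,
        GG_iHH=GG_iHH, pump=pump, stimulus=stimulus, fq_coefficients=fq,
        reference_state=ref, solver=solver, seed=int(raw.get("seed", 0)),
    )


def write_results(obj, path: str | Path, metadata: Optional[Mapping[str, Any]] = None) -> Tuple[Path, Path]:
    """Write a result table as CSV plus a JSON metadata sidecar.

    ``obj`` may be a SimResult, a BifurcationDiagram, or any DataFrame.
    Returns (csv_path, json_path).  The sidecar records the package
    version, a hash of the resolved parameters, and any caller metadata.
    """
    path = Path(path)
    meta: Dict[str, Any] = {"gnpneuro_version": __version__}
    if hasattr(obj, "to_frame"):
        frame = obj.to_frame()
        if hasattr(obj, "definition"):
            meta["variant"] = obj.definition.variant
        elif hasattr(obj, "variant"):
            meta["variant"] = obj.variant
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    if metadata:
        meta.update(metadata)
    blob = json.dumps(meta, sort_keys=True, default=str)
    meta["params_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    frame.to_csv(path, index=False)
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return path, side


def fixtures() -> Dict[str, Any]:
    """The canonical parameter and channel-preset registry.

    Single machine-readable source for every printed constant the package
    relies on: the neuron-model parameter set, the conservation constants,
    channel calibration inputs and resulting single-channel permeabilities,
    and the published fq cubic coefficients.
    """
    gabaa = gabaa_channel()
    ampa = ampa_channel()
    return {
        "constants": {"F_C_per_mol": 96485.33, "R_J_per_mol_K": 8.314, "T_K": 309.15},
        "geometry": {"Cm_uF_per_cm2": 1.0, "S_over_v_per_m": 4.0e5, "A_in_mM": 110.0},
        "sigma_mM": dict(DEFAULT_SIGMA),
        "reference_state": dict(DEFAULT_REFERENCE),
        "P_leak_m_per_s": dict(DEFAULT_P_LEAK),
        "P_glu_m_per_s": dict(DEFAULT_P_GLU),
        "P_gated_m_per_s": dict(DEFAULT_P_GATED),
        "GKM_mS_per_cm2": 20.0,
        "GNaM_mS_per_cm2": 30.0,
        "printed_GG_iHH_mS_per_cm2": dict(PRINTED_GG_IHH),
        "pump": {"M_NaK_mM_per_s": [0.3, 0.7], "I_const_uA_per_cm2": -1.16},
        "fq_coefficients": {k: list(v) for k, v in PRINTED_FQ_COEFFICIENTS.items()},
        "channels": {
            "pore_diameter_m": PORE_DIAMETER_M,
            "single_channel_conductance_pS": 30.0,
            "bath_concentrations_mM": {k: list(v) for k, v in PHYSIOLOGICAL.items()},
            "gabaa": {ion.name: P for ion, P in gabaa.permeants},
            "ampa": {ion.name: P for ion, P in ampa.permeants},
            "ampa_glur2less_extra": {"Ca": P_CA_GLUR2LESS, "Ca_i_mM": 1e-4, "Ca_o_mM": 2.0},
            "leak_single_channel_P_m_per_s": dict(LEAK_SINGLE_CHANNEL_P),
            "densities_per_cm2": {"leak": LEAK_DENSITY_PER_CM2, "ampa": AMPA_DENSITY_PER_CM2},
        },
    }
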