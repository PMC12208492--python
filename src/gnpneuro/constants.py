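"""Physical constants and unit conversions.

Internal computations run in SI (volts, mol/m^3, A/m^2, S/m^2); every public
interface speaks the units electrophysiologists print: mV, mM, uA/cm^2,
mS/cm^2, m/s for permeabilities.  Conveniently 1 mM == 1 mol/m^3, so
concentrations never need converting; voltages, currents and conductances do
(1 V = 1000 mV, 1 A/m^2 = 100 uA/cm^2, 1 S/m^2 = 0.1 mS/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

#: multiply an SI current density (A/m^2) by this to get uA/cm^2
A_PER_M2_TO_UA_PER_CM2 = 100.0
#: multiply an SI conductance density (S/m^2) by this to get mS/cm^2
S_PER_M2_TO_MS_PER_CM2 = 0.1
#: multiply uF/cm^2 by this to get F/m^2
UF_PER_CM2_TO_F_PER_M2 = 0.01


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    Parameters
    ----------
    F : float
        Faraday constant, C/mol.
    R : float
        Gas constant, J/(mol K).
    T : float
        Absolute temperature, K.  Default 309.15 K (36 C).
    """

    F: float = 96485.33
    R: float = 8.314
    T: float = 309.15

    def __post_init__(self) -> None:
        if self.F <= 0 or self.R <= 0 or self.T <= 0:
            raise ValueError("F, R and T must be strictly positive")

    @property
    def RT(self) -> float:
        """R*T in J/mol."""
        return self.R * self.T

    @property
    def vt_mV(self) -> float:
        """Thermal voltage RT/F in mV (~26.64 mV at 309.15 K)."""
        return self.R * self.T / self.F * 1000.0


DEFAULT_CONSTANTS = PhysicalConstants()
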