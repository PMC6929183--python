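"""Temperature and the constants bundle shared by every thermal formula."""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import C2_CM_K, KB_KCAL_MOL_K


@dataclass(frozen=True)
class ThermoSettings:
    """Temperature plus the constant bundle entering u = hcν̃/k_BT.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Defaults to 298.15 K; the batch
        hydrolysis experiments were run at 30 °C (303.15 K), which callers can
        request explicitly.
    kb_kcal : float
        Boltzmann constant in kcal mol^-1 K^-1.
    c2_cm_k : float
        Second radiation constant hc/k_B in cm·K.
    """

    temperature: float = 298.15
    kb_kcal: float = field(default=KB_KCAL_MOL_K)
    c2_cm_k: float = field(default=C2_CM_K)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kt_kcal(self) -> float:
        """k_B T in kcal/mol."""
        return self.kb_kcal * self.temperature

    @property
    def beta(self) -> float:
        """1/(k_B T) in mol/kcal."""
        return 1.0 / self.kt_kcal

    def u(self, wavenumber_cm: float):
        """Dimensionless vibrational parameter u = hcν̃/k_BT."""
        return self.c2_cm_k * wavenumber_cm / self.temperature
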