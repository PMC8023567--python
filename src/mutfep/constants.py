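"""Thermodynamic constants in GROMOS units (kJ/mol, nm, K, elementary charge)."""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ mol^-1 K^-1 (GROMOS convention).
KB_KJ_PER_MOL_K = 0.00831451

#: Default absolute temperature in K.
DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature and Boltzmann constant bundle.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K. Must be positive.
    boltzmann : float
        Boltzmann constant in kJ mol^-1 K^-1.
    """

    temperature: float = DEFAULT_TEMPERATURE_K
    boltzmann: float = KB_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not self.boltzmann > 0:
            raise ValueError(f"boltzmann constant must be positive, got {self.boltzmann}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B * T in kJ/mol."""
        return self.boltzmann * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T) in mol/kJ."""
        return 1.0 / self.kT


DEFAULT_CONSTANTS = ThermoConstants()
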