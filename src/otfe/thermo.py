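"""Thermodynamic state in GROMACS-style units (kJ/mol, nm, ps, amu, K).

In this unit system the Boltzmann constant is 0.00831446 kJ/(mol K), and a
harmonic oscillator of mass ``m`` amu and frequency ``nu`` ps^-1 has spring
constant ``k = m (2 pi nu)^2`` in kJ/(mol nm^2) directly, with no further
conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kJ/(mol K).
KB: float = 0.00831446


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived inverse thermal energy beta = 1/(kB T)."""

    temperature: float = 300.0
    boltzmann_constant: float = KB
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "beta", 1.0 / (self.boltzmann_constant * self.temperature))

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return 1.0 / self.beta
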