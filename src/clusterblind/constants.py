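"""Physical constants and gyromagnetic ratios used throughout the package.

All values are CODATA-2018 SI. A single :class:`PhysicalConstants` record is
shared by the spin-ladder and relaxation modules so unit conventions live in
exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants plus gyromagnetic ratios (rad s^-1 T^-1) by isotope."""

    mu_B: float = 9.2740100783e-24      # Bohr magneton, J/T
    k_B: float = 1.380649e-23           # Boltzmann constant, J/K
    hbar: float = 1.054571817e-34       # reduced Planck constant, J s
    h: float = 6.62607015e-34           # Planck constant, J s
    mu_0: float = 1.25663706212e-6      # vacuum permeability, T m/A
    c_cm: float = 2.99792458e10         # speed of light, cm/s (cm^-1 -> Hz)
    gamma: dict = field(default_factory=lambda: {
        "1H": 2.6752218744e8,
        "15N": -2.7126180e7,
        "13C": 6.728284e7,
    })

    def gamma_of(self, nucleus: str) -> float:
        try:
            return self.gamma[nucleus]
        except KeyError:
            raise ValueError(
                f"unknown nucleus {nucleus!r}; known: {sorted(self.gamma)}"
            ) from None

    def wavenumber_to_joule(self, e_cm: float) -> float:
        """Convert an energy in cm^-1 (spectroscopy convention) to joules."""
        return e_cm * self.h * self.c_cm


CONSTANTS = PhysicalConstants()
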