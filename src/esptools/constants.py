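"""Physical constants used throughout the package.

All spectroscopic energies are handled in wavenumbers (cm^-1), so the
combinations that matter are ``h*c`` in erg*cm (CGS, for the dipole analysis)
and ``h*c/k`` in cm*K (for the Forster cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.constants as _sc


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants (SI) with a default working temperature.

    Attributes
    ----------
    h : Planck constant, J s.
    c : speed of light, m/s.
    k : Boltzmann constant, J/K.
    T_default : default temperature, K.
    """

    h: float = _sc.h
    c: float = _sc.c
    k: float = _sc.k
    T_default: float = 298.0

    def __post_init__(self) -> None:
        if min(self.h, self.c, self.k, self.T_default) <= 0:
            raise ValueError("all physical constants must be positive")

    @property
    def c_cm(self) -> float:
        """Speed of light in cm/s."""
        return self.c * 100.0

    @property
    def hc_over_k_cm_K(self) -> float:
        """h*c/k in cm*K (the 'second radiation constant', ~1.43877 cm K)."""
        return self.h * self.c_cm / self.k

    @property
    def hc_erg_cm(self) -> float:
        """h*c in erg*cm (CGS), ~1.98645e-16."""
        return self.h * 1e7 * self.c_cm

    def forster_coefficient(self, temperature: float | None = None) -> float:
        """h*c/(k*T*ln10) in cm: converts a wavenumber difference to pKa units."""
        T = self.T_default if temperature is None else temperature
        if T <= 0:
            raise ValueError("temperature must be positive")
        return self.hc_over_k_cm_K / (T * math.log(10.0))


CONSTANTS = PhysicalConstants()

#: 1 Debye in esu*cm (CGS electrostatic units).
DEBYE_ESU_CM = 1e-18
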