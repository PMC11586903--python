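"""Forster-cycle estimation of the excited-state pKa*.

The Forster cycle relates the ground- and excited-state protonation
equilibria of a chromophore through the electronic (0,0) transition energies
of its conjugate base (B) and acid (BH) forms:

    pKa* = pKa + [h c / (k T ln10)] * (nu_B - nu_BH)

with the transition energies in wavenumbers (cm^-1). At 298 K the prefactor
h*c/(k*T*ln10) is 2.0966e-3 cm. The cycle assumes the protonation entropy is
the same in both electronic states, so the result is quasi-thermodynamic: a
positive nu_B - nu_BH (the base absorbs/emits at higher energy) means the
excited state is the stronger base. The 0-0 energy of each form is
approximated as the mean of its peak absorption and (lambda^2-corrected)
emission energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .constants import CONSTANTS, PhysicalConstants
from .errors import DataError


@dataclass(frozen=True)
class ForsterInput:
    """Ground-state pKa plus the 0-0 energies of the base/acid pair (cm^-1)."""

    pKa_ground: float
    nu00_base: float
    nu00_acid: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.nu00_base <= 0 or self.nu00_acid <= 0:
            raise DataError("transition energies must be positive")
        if self.temperature <= 0:
            raise DataError("temperature must be positive")


@dataclass(frozen=True)
class ForsterResult:
    pKa_excited: float
    delta_pKa: float


def nu00_estimate(abs_max: float, em_max: float) -> float:
    """0-0 transition energy as the mean of absorption and emission maxima.

    Both inputs in cm^-1; the emission maximum should come from a
    lambda^2-corrected spectrum. Warns if the emission energy exceeds the
    absorption energy (negative Stokes shift).
    """
    if abs_max <= 0 or em_max <= 0:
        raise DataError("transition energies must be positive")
    if abs_max < em_max:
        warnings.warn("absorption maximum below emission maximum "
                      "(negative Stokes shift)", stacklevel=2)
    return 0.5 * (abs_max + em_max)


def excited_pKa(inp: ForsterInput,
                constants: PhysicalConstants = CONSTANTS) -> ForsterResult:
    """Excited-state pKa* from the Forster cycle."""
    coeff = constants.forster_coefficient(inp.temperature)
    shift = coeff * (inp.nu00_base - inp.nu00_acid)
    return ForsterResult(pKa_excited=inp.pKa_ground + shift, delta_pKa=shift)


def delta_orders_of_magnitude(result: ForsterResult) -> float:
    """Basicity change upon excitation in log10 units (= delta pKa)."""
    return result.delta_pKa
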