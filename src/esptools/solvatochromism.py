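"""Lippert-Mataga solvatochromic analysis.

In a dielectric continuum, the Stokes shift of a dipolar fluorophore grows
linearly with the solvent orientation-polarizability function

    delta_f = (eps_r - 1)/(2 eps_r + 1) - (n^2 - 1)/(2 n^2 + 1)

according to the Lippert-Mataga relation

    nu_abs - nu_em = delta_nu_0 + [2 (mu_e - mu_g)^2 / (h c a0^3)] * delta_f

so an ordinary least-squares regression of the Stokes shift on delta_f gives
a slope from which the dipole-moment change upon excitation follows for a
chosen Onsager cavity radius a0:

    mu_e - mu_g = sqrt(slope * h * c * a0^3 / 2)

All dipole arithmetic is done in Gaussian (CGS) units — slope in cm^-1,
h*c in erg*cm, a0 in cm — giving mu in esu*cm, reported in Debye
(1 D = 1e-18 esu*cm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import CONSTANTS, DEBYE_ESU_CM
from .errors import DataError, DegenerateDesignError
from .spectra import (Spectrum, emission_to_wavenumber_scale, nm_to_wavenumber,
                      peak_position, WAVELENGTH_NM, WAVENUMBER_CM)


@dataclass(frozen=True)
class SolventRecord:
    """Solvent dielectric data: relative permittivity and refractive index."""

    name: str
    epsilon_r: float
    n: float

    def __post_init__(self) -> None:
        if self.epsilon_r < 1 or self.n < 1:
            raise DataError(f"{self.name}: epsilon_r and n must be >= 1")


#: Bundled dielectric constants and refractive indices at 20-25 C
#: (CRC Handbook of Chemistry and Physics, 95th ed., sodium D line).
SOLVENT_TABLE: dict[str, SolventRecord] = {r.name: r for r in [
    SolventRecord("dioxane", 2.25, 1.4224),
    SolventRecord("toluene", 2.38, 1.4961),
    SolventRecord("chloroform", 4.81, 1.4459),
    SolventRecord("THF", 7.58, 1.4072),
    SolventRecord("DCM", 8.93, 1.4242),
    SolventRecord("EtOH", 24.5, 1.3611),
    SolventRecord("MeOH", 32.7, 1.3288),
    SolventRecord("MeCN", 35.9, 1.3442),
    SolventRecord("DMF", 36.7, 1.4305),
    SolventRecord("water", 78.36, 1.3330),
]}


@dataclass
class LippertPoint:
    """One solvent's absorption/emission maxima (cm^-1, emission lambda^2-corrected)."""

    solvent: SolventRecord
    nu_abs: float
    nu_em: float

    @property
    def stokes_shift(self) -> float:
        return self.nu_abs - self.nu_em

    @property
    def delta_f(self) -> float:
        return polarity_delta_f(self.solvent)


@dataclass
class LippertFit:
    """Regression summary and derived dipole-moment change."""

    slope: float
    slope_se: float
    intercept: float
    r: float
    onsager_radius_a0: float  # Angstrom
    delta_mu: float  # Debye
    delta_mu_se: float
    points: list[LippertPoint] = field(default_factory=list)


def polarity_delta_f(solvent: SolventRecord) -> float:
    """Orientation polarizability delta_f of a solvent (dimensionless)."""
    e, n2 = solvent.epsilon_r, solvent.n**2
    return (e - 1) / (2 * e + 1) - (n2 - 1) / (2 * n2 + 1)


def lippert_regression(points: Sequence[LippertPoint]):
    """OLS regression of Stokes shift on delta_f.

    Returns ``(slope, intercept, r, slope_se)`` in cm^-1 (slope, intercept).
    """
    if len(points) < 3:
        raise DegenerateDesignError("need >= 3 solvents for the regression")
    x = np.array([p.delta_f for p in points])
    y = np.array([p.stokes_shift for p in points])
    if np.ptp(x) < 1e-12:
        raise DegenerateDesignError("no variation in solvent polarity delta_f")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.stderr)


def dipole_change(slope: float, a0_angstrom: float,
                  slope_se: float = 0.0) -> tuple[float, float]:
    """Dipole-moment change (Debye) from the Lippert slope and Onsager radius.

    ``slope`` in cm^-1, ``a0_angstrom`` in Angstrom. A negative slope is
    unphysical for a dipole increase: a warning is emitted and 0 returned.
    The standard error follows from the delta method,
    se(mu) = mu * se(slope) / (2 slope).

    Returns ``(delta_mu_debye, delta_mu_se_debye)``.
    """
    if a0_angstrom <= 0:
        raise DataError("Onsager radius must be positive")
    if slope < 0:
        warnings.warn("negative Lippert slope; returning delta_mu = 0",
                      stacklevel=2)
        return 0.0, 0.0
    a0_cm = a0_angstrom * 1e-8
    mu_esu = math.sqrt(slope * CONSTANTS.hc_erg_cm * a0_cm**3 / 2.0)
    mu_d = mu_esu / DEBYE_ESU_CM
    se_d = mu_d * slope_se / (2.0 * slope) if slope > 0 else 0.0
    return mu_d, se_d


def _nu_from_pair(abs_spec: Spectrum, em_spec: Spectrum) -> tuple[float, float]:
    """Absorption and lambda^2-corrected emission maxima in cm^-1."""
    if abs_spec.axis_kind == WAVELENGTH_NM:
        nu_abs = nm_to_wavenumber(peak_position(abs_spec))
    else:
        nu_abs = peak_position(abs_spec)
    if em_spec.axis_kind == WAVELENGTH_NM:
        em_corr = emission_to_wavenumber_scale(em_spec)
    elif em_spec.axis_kind == WAVENUMBER_CM:
        em_corr = em_spec
    nu_em = peak_position(em_corr)
    return nu_abs, nu_em


def analyze_solvent_series(pairs: Mapping[str, tuple[Spectrum, Spectrum]],
                           a0_angstrom: float,
                           solvent_table: Mapping[str, SolventRecord] | None = None
                           ) -> LippertFit:
    """Full Lippert-Mataga pipeline over a solvent series.

    ``pairs`` maps solvent name -> (absorption spectrum, emission spectrum);
    each emission spectrum is lambda^2-corrected before its maximum is
    located. Solvent names are resolved in ``solvent_table`` (default: the
    bundled table).
    """
    table = SOLVENT_TABLE if solvent_table is None else solvent_table
    points: list[LippertPoint] = []
    for name, (abs_spec, em_spec) in pairs.items():
        if name not in table:
            raise DataError(f"no dielectric parameters for solvent {name!r}")
        nu_abs, nu_em = _nu_from_pair(abs_spec, em_spec)
        points.append(LippertPoint(table[name], nu_abs, nu_em))
    slope, intercept, r, se = lippert_regression(points)
    mu, mu_se = dipole_change(slope, a0_angstrom, se)
    return LippertFit(slope, se, intercept, r, a0_angstrom, mu, mu_se, points)
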