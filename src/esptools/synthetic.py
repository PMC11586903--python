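"""Synthetic-data generators for every stage of the pipeline.

The generators produce inputs with exactly the statistical structure the
analysis assumes, so that each fitting stage can be exercised against a known
ground truth without instrument data:

* titrations: Gaussian-band component spectra combined through
  Henderson-Hasselbalch speciation fractions (Beer-Lambert bilinearity) with
  additive Gaussian absorbance noise;
* solvent series: absorption/emission pairs whose Stokes shifts are exactly
  linear in the Onsager polarity function delta_f, the emission band being
  Gaussian on the (lambda^2-corrected) wavenumber scale;
* decays: monoexponential bin expectations sampled with Poisson noise.

Every generator takes a seed and is bit-reproducible; each returns the
generated object together with a ``truth`` dict recording the generating
parameters.

Presets encode the study scenarios of the push-pull pyridine photobase
fluorophores this package was written around (protonation shifts
346 -> 397 nm and 345 -> 386 nm, emission 489 -> 581 nm, lifetimes
2.64 / 3.13 ns in H2O / D2O, dipole changes 10.8 / 7.3 D), with band widths
and amplitude ratios chosen as structural stand-ins for unpublished raw
spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, DEBYE_ESU_CM
from .errors import ConfigError
from .solvatochromism import SOLVENT_TABLE, SolventRecord, polarity_delta_f
from .spectra import ABSORBANCE, EMISSION, Spectrum, WAVELENGTH_NM
from .titration import ProtonationModel, TitrationSeries, species_fractions
from .kinetics import DecayHistogram

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian band: center and FWHM in nm, amplitude in molar response."""

    center_nm: float
    fwhm_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if min(self.center_nm, self.fwhm_nm, self.amplitude) <= 0:
            raise ConfigError("BandSpec fields must all be positive")

    def profile(self, lam: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_nm * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(-0.5 * ((lam - self.center_nm) / sigma) ** 2)


def _band_sum(bands: Sequence[BandSpec], lam: np.ndarray) -> np.ndarray:
    out = np.zeros_like(lam)
    for b in bands:
        out += b.profile(lam)
    return out


def gen_titration(pkas: Sequence[float],
                  bands_per_species: Sequence[Sequence[BandSpec]],
                  ph_values: Sequence[float],
                  grid: tuple[float, float, float] = (250.0, 500.0, 1.0),
                  path_length: float = 1.0,
                  total_conc: float = 1e-5,
                  noise_sigma: float = 0.002,
                  response_kind: str = ABSORBANCE,
                  seed: int = 0) -> tuple[TitrationSeries, dict]:
    """Bilinear titration matrix A(pH, lambda) with Gaussian noise.

    ``bands_per_species`` lists the Gaussian bands of each protonation state,
    ordered from fully deprotonated to fully protonated (len = n_pKa + 1).
    For emission data ``noise_sigma`` is interpreted as a fraction of the
    peak clean intensity (relative noise); for absorbance it is absolute AU.
    """
    pkas = list(pkas)
    if len(bands_per_species) != len(pkas) + 1:
        raise ConfigError("bands_per_species must list n_pKa + 1 species")
    if len(bands_per_species) < 2:
        raise ConfigError("need >= 2 species band specs")
    ph_values = np.asarray(ph_values, dtype=float)
    if ph_values.size == 0:
        raise ConfigError("ph_values is empty")
    start, stop, step = grid
    lam = np.arange(start, stop + step / 2, step)
    if lam.size < 3:
        raise ConfigError("grid yields fewer than 3 wavelength points")
    E = np.vstack([_band_sum(b, lam) for b in bands_per_species])
    model = ProtonationModel(np.asarray(pkas))
    F = species_fractions(model, ph_values)
    clean = F @ (total_conc * path_length * E)
    rng = np.random.default_rng(seed)
    sigma = noise_sigma * clean.max() if response_kind == EMISSION else noise_sigma
    noisy = clean + rng.normal(0.0, sigma, clean.shape) if sigma > 0 else clean
    series = TitrationSeries(ph_values, noisy, lam, path_length, total_conc,
                             response_kind)
    truth = {"pKa": pkas, "component_spectra": E, "axis": lam,
             "clean_matrix": clean, "noise_sigma": float(sigma), "seed": seed}
    return series, truth


def gen_solvent_series(solvents: Sequence[SolventRecord],
                       delta_mu_debye: float,
                       a0_angstrom: float,
                       nu_abs: float = 28600.0,
                       delta_nu0: float = 3900.0,
                       abs_fwhm_nm: float = 60.0,
                       em_fwhm_cm: float = 3500.0,
                       jitter_cm: float = 0.0,
                       grid_step_nm: float = 0.5,
                       seed: int = 0) -> tuple[dict, dict]:
    """Per-solvent absorption/emission spectrum pairs obeying Lippert-Mataga.

    Each solvent's Stokes shift is delta_nu0 + slope * delta_f with
    slope = 2 (mu_e - mu_g)^2 / (h c a0^3) in cm^-1. The absorption band is
    Gaussian in wavelength at nu_abs; the emission trace is constructed so
    that its lambda^2-corrected form is a Gaussian in wavenumber centered at
    nu_abs - stokes (i.e. the generator defines the corrected-band truth).
    ``jitter_cm`` adds Gaussian noise to both maxima per solvent.

    Returns (pairs, truth) where pairs maps solvent name -> (abs, em)
    :class:`Spectrum` and truth records the slope and per-solvent maxima.
    """
    if len(solvents) == 0:
        raise ConfigError("empty solvent list")
    if a0_angstrom <= 0 or delta_mu_debye < 0:
        raise ConfigError("a0 must be positive and delta_mu non-negative")
    mu_esu = delta_mu_debye * DEBYE_ESU_CM
    a0_cm = a0_angstrom * 1e-8
    slope = 2.0 * mu_esu**2 / (CONSTANTS.hc_erg_cm * a0_cm**3)
    rng = np.random.default_rng(seed)
    pairs: dict[str, tuple[Spectrum, Spectrum]] = {}
    per_solvent = {}
    for sol in solvents:
        df = polarity_delta_f(sol)
        na = nu_abs + (rng.normal(0.0, jitter_cm) if jitter_cm > 0 else 0.0)
        ne = na - (delta_nu0 + slope * df) \
            + (rng.normal(0.0, jitter_cm) if jitter_cm > 0 else 0.0)
        lam_abs_c = 1e7 / na
        lam = np.arange(lam_abs_c - 3 * abs_fwhm_nm, lam_abs_c + 3 * abs_fwhm_nm,
                        grid_step_nm)
        abs_spec = Spectrum(lam, BandSpec(lam_abs_c, abs_fwhm_nm, 1.0).profile(lam),
                            WAVELENGTH_NM, ABSORBANCE, label=f"{sol.name}-abs",
                            meta={"solvent": sol.name})
        lam_em_c = 1e7 / ne
        lam_e = np.arange(lam_em_c * 0.75, lam_em_c * 1.4, grid_step_nm)
        nu_e = 1e7 / lam_e
        sigma_nu = em_fwhm_cm * _FWHM_TO_SIGMA
        corrected = np.exp(-0.5 * ((nu_e - ne) / sigma_nu) ** 2)
        em_signal = corrected / lam_e**2
        em_spec = Spectrum(lam_e, em_signal / em_signal.max(), WAVELENGTH_NM,
                           EMISSION, label=f"{sol.name}-em",
                           meta={"solvent": sol.name})
        pairs[sol.name] = (abs_spec, em_spec)
        per_solvent[sol.name] = {"delta_f": df, "nu_abs": na, "nu_em": ne,
                                 "stokes": na - ne}
    truth = {"slope": slope, "delta_nu0": delta_nu0,
             "delta_mu_debye": delta_mu_debye, "a0_angstrom": a0_angstrom,
             "per_solvent": per_solvent, "seed": seed}
    return pairs, truth


def gen_decay(tau_ns: float,
              counts_total: float = 1e5,
              t_max_ns: float = 25.0,
              bin_ns: float = 0.05,
              baseline_fraction: float = 0.0,
              noiseless: bool = False,
              seed: int = 0) -> tuple[DecayHistogram, dict]:
    """Monoexponential decay histogram with Poisson counting noise.

    Bin expectations are A exp(-t/tau) + B with A scaled so the expected
    total equals ``counts_total`` and B = baseline_fraction * A. With
    ``noiseless=True`` the exact (real-valued) expectations are returned.
    """
    if tau_ns <= 0:
        raise ConfigError("tau must be positive")
    if counts_total < 1e3:
        raise ConfigError("counts_total must be >= 1e3")
    t = np.arange(0.0, t_max_ns, bin_ns)
    shape = np.exp(-t / tau_ns)
    A = counts_total / (shape.sum() * (1.0 + baseline_fraction * t.size / shape.sum()))
    B = baseline_fraction * A
    expectations = A * shape + B
    if noiseless:
        counts = expectations
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expectations).astype(float)
    hist = DecayHistogram(t, counts)
    truth = {"tau_ns": tau_ns, "amplitude": A, "baseline": B,
             "counts_total": counts_total, "seed": seed}
    return hist, truth


# ---------------------------------------------------------------------------
# Presets: study scenarios with parameters drawn from the published tables.
# Band FWHMs (60 nm absorption, 90 nm emission) and emission amplitude ratios
# are structural stand-ins typical of charge-transfer bands.
# ---------------------------------------------------------------------------

_LIPPERT_SOLVENTS = [SOLVENT_TABLE[s] for s in
                     ("dioxane", "toluene", "chloroform", "THF", "DCM",
                      "EtOH", "MeOH", "MeCN")]

PRESETS: dict[str, dict] = {
    # two-species absorbance titration of the 1b pyridine photobase
    "1b-abs": dict(kind="titration", pkas=[4.49],
                   bands=[[BandSpec(346.0, 60.0, 2.3e4)],
                          [BandSpec(397.0, 60.0, 2.5e4)]],
                   ph=np.linspace(3.2, 5.6, 12), grid=(250.0, 500.0, 1.0),
                   noise_sigma=0.002, response_kind=ABSORBANCE),
    # emission titration of 1b excited at the isosbestic point
    "1b-em": dict(kind="titration", pkas=[4.51],
                  bands=[[BandSpec(489.0, 90.0, 1.0)],
                         [BandSpec(581.0, 90.0, 0.8)]],
                  ph=np.linspace(3.2, 5.6, 12), grid=(420.0, 700.0, 1.0),
                  noise_sigma=0.01, response_kind=EMISSION,
                  total_conc=1.0),
    # two-species absorbance titration of the redesigned 5b core
    "5b-abs": dict(kind="titration", pkas=[2.34],
                   bands=[[BandSpec(345.0, 60.0, 2.3e4)],
                          [BandSpec(386.0, 60.0, 2.1e4)]],
                   ph=np.linspace(1.3, 4.0, 12), grid=(250.0, 500.0, 1.0),
                   noise_sigma=0.002, response_kind=ABSORBANCE),
    # triprotic carboxylate/pyridinium ladder of the chromis-1 probe
    "chromis1": dict(kind="titration", pkas=[5.5, 3.5, 1.2],
                     bands=[[BandSpec(335.0, 45.0, 2.2e4)],
                            [BandSpec(365.0, 45.0, 2.3e4)],
                            [BandSpec(392.0, 45.0, 2.4e4)],
                            [BandSpec(418.0, 45.0, 2.5e4)]],
                     ph=np.linspace(0.0, 8.0, 16), grid=(250.0, 500.0, 1.0),
                     noise_sigma=0.002, response_kind=ABSORBANCE),
    # TCSPC decays of 1b in light and heavy water
    "1b-H2O": dict(kind="decay", tau_ns=2.64, counts_total=1e5),
    "1b-D2O": dict(kind="decay", tau_ns=3.13, counts_total=1e5),
    # solvent series of the charge-neutral cores
    "lippert-1a": dict(kind="lippert", delta_mu_debye=10.8, a0_angstrom=5.04,
                       nu_abs=28600.0, delta_nu0=3900.0,
                       solvents=_LIPPERT_SOLVENTS),
    "lippert-5a": dict(kind="lippert", delta_mu_debye=7.3, a0_angstrom=5.07,
                       nu_abs=28900.0, delta_nu0=3000.0,
                       solvents=_LIPPERT_SOLVENTS),
}


def generate_preset(name: str, seed: int = 0, **overrides):
    """Generate a preset scenario; returns (object, truth).

    ``overrides`` replace preset parameters (e.g. ``noise_sigma=0``).
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: "
                          f"{sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    kind = cfg.pop("kind")
    cfg.update(overrides)
    if kind == "titration":
        return gen_titration(cfg["pkas"], cfg["bands"], cfg["ph"],
                             grid=cfg.get("grid", (250.0, 500.0, 1.0)),
                             total_conc=cfg.get("total_conc", 1e-5),
                             path_length=cfg.get("path_length", 1.0),
                             noise_sigma=cfg.get("noise_sigma", 0.002),
                             response_kind=cfg.get("response_kind", ABSORBANCE),
                             seed=seed)
    if kind == "decay":
        return gen_decay(cfg["tau_ns"], counts_total=cfg.get("counts_total", 1e5),
                         t_max_ns=cfg.get("t_max_ns", 25.0),
                         bin_ns=cfg.get("bin_ns", 0.05),
                         baseline_fraction=cfg.get("baseline_fraction", 0.0),
                         noiseless=cfg.get("noiseless", False), seed=seed)
    if kind == "lippert":
        return gen_solvent_series(cfg["solvents"], cfg["delta_mu_debye"],
                                  cfg["a0_angstrom"], nu_abs=cfg["nu_abs"],
                                  delta_nu0=cfg["delta_nu0"],
                                  jitter_cm=cfg.get("jitter_cm", 0.0), seed=seed)
    raise ConfigError(f"unknown preset kind {kind!r}")


def isosbestic_amplitude_ratio(center1: float, center2: float, fwhm: float,
                               crossing: float) -> float:
    """Amplitude ratio A1/A2 placing the crossing of two equal-width Gaussian
    bands at a chosen wavelength (used to construct exact isosbestic fixtures)."""
    sigma = fwhm * _FWHM_TO_SIGMA
    return math.exp(((crossing - center1) ** 2 - (crossing - center2) ** 2)
                    / (2.0 * sigma**2))
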