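"""Speciation model and global multiwavelength titration fitting.

The protonation chemistry is a ladder of stepwise equilibria
``B + j H+ <-> BH_j`` with stepwise constants pKa_1 >= pKa_2 >= ... (the first
constant belongs to the most basic site). At a given pH the fractional
population of the species carrying j extra protons follows from the
cumulative formation constants beta_j = 10^(pKa_1 + ... + pKa_j):

    f_j(pH) = beta_j 10^(-j pH) / sum_m beta_m 10^(-m pH)

A spectrophotometric titration obeys Beer-Lambert bilinearity,
A(pH, lambda) = sum_j f_j(pH) * c_tot * l * eps_j(lambda), so the global fit
is a separable (variable-projection) least-squares problem: for any trial pKa
vector the component spectra solve a linear problem, and only the pKa vector
is optimized nonlinearly. This mirrors the global-analysis strategy of
SPECFIT-style software.

Proton activity is taken as 10^(-pH) with no activity-coefficient correction
(appropriate for titrations at fixed ionic strength reporting
concentration-scale p[H]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import DataError, SingularityError, UnidentifiableError
from .spectra import ABSORBANCE, EMISSION

_RESPONSE_KINDS = (ABSORBANCE, EMISSION)


@dataclass
class ProtonationModel:
    """Stepwise protonation ladder defined by its pKa values.

    ``pKa_list`` is ordered from the first (most basic) to the last site;
    the model has ``len(pKa_list) + 1`` species. Non-descending values are
    physically unusual (cooperative binding) and trigger a warning.
    """

    pKa_list: np.ndarray

    def __post_init__(self) -> None:
        self.pKa_list = np.atleast_1d(np.asarray(self.pKa_list, dtype=float))
        if not np.all(np.isfinite(self.pKa_list)):
            raise DataError("pKa values must be finite")
        if self.pKa_list.size > 1 and np.any(np.diff(self.pKa_list) > 0):
            warnings.warn("pKa values are not in descending order", stacklevel=2)

    @property
    def n_species(self) -> int:
        return self.pKa_list.size + 1


def species_fractions(model: ProtonationModel, pH) -> np.ndarray:
    """Fractional populations of each protonation state at the given pH.

    Returns an array of shape ``(n_species,)`` for scalar pH, else
    ``(n_pH, n_species)``; column j is the species carrying j extra protons
    (column 0 = fully deprotonated). Rows sum to 1. Evaluated in log10 space
    for numerical stability at extreme pH.
    """
    pH_arr = np.atleast_1d(np.asarray(pH, dtype=float))
    cum = np.concatenate([[0.0], np.cumsum(model.pKa_list)])  # log10 beta_j
    j = np.arange(model.n_species)
    logw = cum[None, :] - np.outer(pH_arr, j)
    logw -= logw.max(axis=1, keepdims=True)
    w = 10.0 ** logw
    frac = w / w.sum(axis=1, keepdims=True)
    return frac[0] if np.isscalar(pH) or np.ndim(pH) == 0 else frac


@dataclass
class TitrationSeries:
    """pH-dependent response matrix from a spectrophotometric titration.

    ``response_matrix`` has one row per pH value on a common wavelength axis
    (nm). Dilution correction is assumed already applied.
    """

    pH_values: np.ndarray
    response_matrix: np.ndarray
    axis: np.ndarray
    path_length: float = 1.0
    total_conc: float = 1e-5
    response_kind: str = ABSORBANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pH_values = np.asarray(self.pH_values, dtype=float)
        self.response_matrix = np.asarray(self.response_matrix, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.response_matrix.shape != (self.pH_values.size, self.axis.size):
            raise DataError("response matrix shape must be (n_pH, n_wavelength)")
        if np.unique(self.pH_values).size != self.pH_values.size:
            raise DataError("duplicate pH values in series")
        if not np.all(np.isfinite(self.response_matrix)):
            raise DataError("response matrix must be finite")
        if self.response_kind not in _RESPONSE_KINDS:
            raise DataError(f"unknown response_kind {self.response_kind!r}")
        order = np.argsort(self.pH_values)
        self.pH_values = self.pH_values[order]
        self.response_matrix = self.response_matrix[order]


@dataclass
class SpeciationFit:
    """Result of a global titration fit.

    ``component_spectra`` holds the per-species molar response (molar
    absorptivity for absorbance data) on the series' wavelength axis, one row
    per species ordered from fully deprotonated to fully protonated.
    """

    pKa_estimates: np.ndarray
    pKa_se: np.ndarray
    component_spectra: np.ndarray
    residual_rms: float
    axis: np.ndarray
    covariance: np.ndarray | None = None

    @property
    def model(self) -> ProtonationModel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ProtonationModel(self.pKa_estimates)

    def species_distribution(self, pH_grid: np.ndarray) -> np.ndarray:
        """Fraction matrix (n_pH x n_species) over an arbitrary pH grid."""
        return species_fractions(self.model, np.asarray(pH_grid, dtype=float))


def _projected_sse(pkas: np.ndarray, series: TitrationSeries,
                   nonneg: bool) -> tuple[float, np.ndarray]:
    """Separable objective: solve the linear spectra subproblem at fixed pKa.

    Returns the sum of squared residuals and the component spectra (molar
    response) that attain it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ProtonationModel(pkas)
    F = species_fractions(model, series.pH_values)  # n_pH x n_s
    design = F * (series.total_conc * series.path_length)
    if nonneg:
        from scipy.optimize import nnls
        E = np.empty((design.shape[1], series.axis.size))
        sse = 0.0
        for j in range(series.axis.size):
            E[:, j], rnorm = nnls(design, series.response_matrix[:, j])
            sse += rnorm**2
        return sse, E
    E, _, rank, _ = np.linalg.lstsq(design, series.response_matrix, rcond=None)
    if rank < design.shape[1]:
        raise SingularityError("species-fraction design is rank deficient")
    resid = series.response_matrix - design @ E
    return float(np.sum(resid**2)), E


def _check_informative(series: TitrationSeries, n_species: int) -> None:
    s = np.linalg.svd(series.response_matrix, compute_uv=False)
    if s.size < n_species or s[n_species - 1] < 1e-10 * s[0]:
        raise SingularityError(
            "response matrix carries fewer independent components than species; "
            "spectra do not change across the series")


def _require_absorbance_or_asserted(series: TitrationSeries,
                                    assume_isosbestic_excitation: bool) -> None:
    if series.response_kind == EMISSION and not assume_isosbestic_excitation:
        raise DataError(
            "emission titrations are bilinear only when excited at an isosbestic "
            "point; pass assume_isosbestic_excitation=True to assert this")


def fit_single_equilibrium(series: TitrationSeries,
                           pKa_bounds: tuple[float, float] | None = None,
                           nonneg: bool = False,
                           assume_isosbestic_excitation: bool = False,
                           n_bootstrap: int = 0,
                           rng=None) -> SpeciationFit:
    """Fit a two-species (single protonation step) model to a titration.

    The scalar pKa is found by bounded 1-D minimization of the projected
    least-squares objective; at each trial pKa the two component spectra are
    the exact linear solution. The standard error combines the curvature of
    the profiled objective with the residual variance; optionally a bootstrap
    over pH points (``n_bootstrap`` resamples) is run instead.

    Raises
    ------
    UnidentifiableError
        if the optimum sticks to the boundary of ``pKa_bounds`` (transition
        outside the sampled window).
    SingularityError
        if the response matrix shows no spectral change across the series.
    """
    _require_absorbance_or_asserted(series, assume_isosbestic_excitation)
    if series.pH_values.size < 4:
        raise DataError("need >= 4 pH points for a single-equilibrium fit")
    _check_informative(series, 2)
    lo, hi = pKa_bounds if pKa_bounds is not None else (
        float(series.pH_values.min()), float(series.pH_values.max()))
    obj = lambda p: _projected_sse(np.array([p]), series, nonneg)[0]
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    pka = float(res.x)
    margin = 1e-3 * (hi - lo)
    if pka - lo < margin or hi - pka < margin:
        raise UnidentifiableError(
            f"fitted pKa {pka:.3f} sits at the boundary of [{lo:g}, {hi:g}]; "
            "the transition is not inside the sampled pH window")
    sse, E = _projected_sse(np.array([pka]), series, nonneg)
    n_obs = series.response_matrix.size
    n_par = 1 + 2 * series.axis.size
    dof = max(n_obs - n_par, 1)
    sigma2 = sse / dof
    h = 1e-4
    d2 = (obj(pka + h) - 2.0 * sse + obj(pka - h)) / h**2
    se = float(np.sqrt(2.0 * sigma2 / d2)) if d2 > 0 else np.inf
    if n_bootstrap > 0:
        rng = np.random.default_rng(rng)
        n = series.pH_values.size
        boot = []
        for _ in range(n_bootstrap):
            idx = np.unique(rng.integers(0, n, size=n))
            if idx.size < 4:
                continue
            sub = TitrationSeries(series.pH_values[idx],
                                  series.response_matrix[idx], series.axis,
                                  series.path_length, series.total_conc,
                                  series.response_kind)
            try:
                r = minimize_scalar(
                    lambda p: _projected_sse(np.array([p]), sub, nonneg)[0],
                    bounds=(lo, hi), method="bounded")
                boot.append(float(r.x))
            except (SingularityError, np.linalg.LinAlgError):
                continue
        if len(boot) >= 10:
            se = float(np.std(boot, ddof=1))
    return SpeciationFit(np.array([pka]), np.array([se]), E,
                         float(np.sqrt(sse / n_obs)), series.axis.copy(),
                         covariance=np.array([[se**2]]))


def fit_multi_equilibrium(series: TitrationSeries, n_steps: int,
                          pKa_bounds: tuple[float, float] | None = None,
                          x0: Sequence[float] | None = None,
                          nonneg: bool = False,
                          assume_isosbestic_excitation: bool = False) -> SpeciationFit:
    """Fit a ladder of ``n_steps`` protonation equilibria globally.

    Same separable objective as :func:`fit_single_equilibrium` with
    ``n_steps + 1`` species; the pKa vector is optimized by Nelder-Mead from
    ``x0`` (default: evenly spaced across the sampled pH window). Trial
    vectors are sorted descending inside the objective, so the landscape is
    permutation-symmetric and the returned estimates are ordered. With
    ``n_steps == 1`` this delegates to the single-equilibrium path.
    """
    if n_steps < 1:
        raise DataError("n_steps must be >= 1")
    if n_steps == 1:
        return fit_single_equilibrium(series, pKa_bounds, nonneg,
                                      assume_isosbestic_excitation)
    _require_absorbance_or_asserted(series, assume_isosbestic_excitation)
    if series.pH_values.size < 3 * n_steps:
        raise DataError(f"need >= {3 * n_steps} pH points for {n_steps} steps")
    _check_informative(series, n_steps + 1)
    lo, hi = pKa_bounds if pKa_bounds is not None else (
        float(series.pH_values.min()), float(series.pH_values.max()))
    if x0 is None:
        x0 = np.linspace(hi, lo, n_steps + 2)[1:-1]
    x0 = np.asarray(x0, dtype=float)

    def obj(p: np.ndarray) -> float:
        p = np.clip(p, lo, hi)
        return _projected_sse(np.sort(p)[::-1], series, nonneg)[0]

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 4000})
    pkas = np.sort(np.clip(res.x, lo, hi))[::-1]
    if np.any(np.diff(res.x) > 0):
        warnings.warn("pKa estimates were non-monotone and have been sorted "
                      "descending", stacklevel=2)
    sse, E = _projected_sse(pkas, series, nonneg)
    n_obs = series.response_matrix.size
    n_par = n_steps + (n_steps + 1) * series.axis.size
    sigma2 = sse / max(n_obs - n_par, 1)
    # numeric Hessian of the profiled objective for standard errors
    h = 1e-4
    H = np.empty((n_steps, n_steps))
    f0 = sse
    for a in range(n_steps):
        for b in range(a, n_steps):
            ea = np.eye(n_steps)[a] * h
            eb = np.eye(n_steps)[b] * h
            if a == b:
                H[a, a] = (obj(pkas + ea) - 2 * f0 + obj(pkas - ea)) / h**2
            else:
                H[a, b] = H[b, a] = (obj(pkas + ea + eb) - obj(pkas + ea - eb)
                                     - obj(pkas - ea + eb) + obj(pkas - ea - eb)
                                     ) / (4 * h**2)
    try:
        cov = 2.0 * sigma2 * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov, se = None, np.full(n_steps, np.inf)
    return SpeciationFit(pkas, se, E, float(np.sqrt(sse / n_obs)),
                         series.axis.copy(), covariance=cov)


def rank_estimate(series: TitrationSeries, threshold: float = 0.1) -> int:
    """Number of spectroscopically distinct species by singular-value count.

    Counts singular values of the response matrix above
    ``threshold * s_max`` — the factor-analysis diagnostic used to confirm
    how many absorbing species a titration family contains.
    """
    if series.response_matrix.size == 0:
        raise DataError("empty response matrix")
    s = np.linalg.svd(series.response_matrix, compute_uv=False)
    if s[0] == 0:
        return 0
    return int(np.sum(s > threshold * s[0]))
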