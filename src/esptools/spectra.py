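"""Spectral data model and elementary spectral operations.

A :class:`Spectrum` is a single absorption or emission trace on a strictly
monotone axis in either wavelength (nm) or wavenumber (cm^-1). The module
provides the nm <-> cm^-1 conversion, the lambda^2 Jacobian correction that
turns an emission spectrum recorded per unit wavelength into one per unit
wavenumber, sub-grid peak location, and isosbestic-point detection for
titration families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AxisAlignmentError, DataError

WAVELENGTH_NM = "wavelength_nm"
WAVENUMBER_CM = "wavenumber_cm-1"
ABSORBANCE = "absorbance"
EMISSION = "emission_intensity"

_AXIS_KINDS = (WAVELENGTH_NM, WAVENUMBER_CM)
_SIGNAL_KINDS = (ABSORBANCE, EMISSION)


@dataclass
class Spectrum:
    """One absorption or emission trace.

    Parameters
    ----------
    axis : strictly monotone grid, nm or cm^-1.
    signal : real values, same length as ``axis``.
    axis_kind : ``"wavelength_nm"`` or ``"wavenumber_cm-1"``.
    signal_kind : ``"absorbance"`` or ``"emission_intensity"``.
    label : free-text identifier.
    meta : key/value metadata (solvent, pH, temperature, ...).
    """

    axis: np.ndarray
    signal: np.ndarray
    axis_kind: str = WAVELENGTH_NM
    signal_kind: str = ABSORBANCE
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.axis.ndim != 1 or self.signal.ndim != 1:
            raise DataError("axis and signal must be one-dimensional")
        if self.axis.size != self.signal.size or self.axis.size < 3:
            raise DataError("axis and signal must have equal length >= 3")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataError("axis must be strictly monotone")
        if self.axis_kind not in _AXIS_KINDS:
            raise DataError(f"unknown axis_kind {self.axis_kind!r}")
        if self.signal_kind not in _SIGNAL_KINDS:
            raise DataError(f"unknown signal_kind {self.signal_kind!r}")
        if self.axis_kind == WAVELENGTH_NM and np.any(self.axis <= 0):
            raise DataError("wavelength axis must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise DataError("signal must be finite")

    def ascending(self) -> "Spectrum":
        """Return a copy with the axis sorted ascending."""
        if self.axis[0] < self.axis[-1]:
            return Spectrum(self.axis.copy(), self.signal.copy(), self.axis_kind,
                            self.signal_kind, self.label, dict(self.meta))
        return Spectrum(self.axis[::-1].copy(), self.signal[::-1].copy(),
                        self.axis_kind, self.signal_kind, self.label, dict(self.meta))


def nm_to_wavenumber(lambda_nm):
    """Convert wavelength (nm) to wavenumber (cm^-1): nu = 1e7 / lambda."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise DataError("wavelength must be positive")
    out = 1e7 / lam
    return float(out) if np.isscalar(lambda_nm) or out.ndim == 0 else out


def wavenumber_to_nm(nu_cm):
    """Convert wavenumber (cm^-1) to wavelength (nm); the same involution."""
    return nm_to_wavenumber(nu_cm)


def emission_to_wavenumber_scale(spec: Spectrum) -> Spectrum:
    """Convert an emission spectrum from a nm axis to a cm^-1 axis.

    An emission spectrum recorded per unit wavelength must be multiplied by
    lambda^2 when re-plotted per unit wavenumber (the Jacobian
    |d lambda / d nu| is proportional to lambda^2). The returned signal is the
    unnormalized I(lambda)*lambda^2; the band integral over nu is proportional
    to the integral over lambda, and the apex shifts to the red of the naive
    1e7/lambda_max conversion.
    """
    if spec.signal_kind != EMISSION:
        raise DataError("lambda^2 correction applies only to emission spectra")
    if spec.axis_kind != WAVELENGTH_NM:
        raise DataError("input must be on a wavelength (nm) axis")
    nu = 1e7 / spec.axis
    corrected = spec.signal * spec.axis**2
    order = np.argsort(nu)
    return Spectrum(nu[order], corrected[order], WAVENUMBER_CM, EMISSION,
                    spec.label, dict(spec.meta))


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three (x, y) points."""
    x1, x2, x3 = x
    y1, y2, y3 = y
    num = (x2 - x1) ** 2 * (y2 - y3) - (x2 - x3) ** 2 * (y2 - y1)
    den = (x2 - x1) * (y2 - y3) - (x2 - x3) * (y2 - y1)
    if den == 0:
        return float(x2)
    return float(x2 - 0.5 * num / den)


def peak_position(spec: Spectrum) -> float:
    """Axis position of the band maximum, interpolated to sub-grid accuracy.

    Fits a parabola through the three points bracketing the discrete maximum
    (ties broken toward the lower index). If the maximum sits on the grid
    boundary a warning is emitted and the boundary axis value returned.
    """
    i = int(np.argmax(spec.signal))
    if i == 0 or i == spec.signal.size - 1:
        warnings.warn("band maximum at grid boundary; returning boundary value",
                      stacklevel=2)
        return float(spec.axis[i])
    return _parabolic_vertex(spec.axis[i - 1:i + 2], spec.signal[i - 1:i + 2])


def resample_to_common_axis(spectra: Sequence[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a series onto the first spectrum's axis.

    Linear interpolation; extrapolation is forbidden — every spectrum must
    cover the first spectrum's axis range.

    Returns
    -------
    axis : the common (first spectrum's) axis, ascending.
    matrix : len(spectra) x len(axis) signal matrix.
    """
    if len(spectra) == 0:
        raise DataError("empty spectrum series")
    kinds = {s.axis_kind for s in spectra}
    if len(kinds) > 1:
        raise AxisAlignmentError("mixed axis kinds in series")
    ref = spectra[0].ascending()
    rows = [ref.signal]
    for s in spectra[1:]:
        s = s.ascending()
        if s.axis[0] > ref.axis[0] + 1e-12 or s.axis[-1] < ref.axis[-1] - 1e-12:
            raise AxisAlignmentError(
                f"spectrum {s.label!r} does not cover the reference axis range "
                f"[{ref.axis[0]:g}, {ref.axis[-1]:g}]")
        rows.append(np.interp(ref.axis, s.axis, s.signal))
    return ref.axis, np.vstack(rows)


def isosbestic_points(series: Iterable[Spectrum], tolerance: float = 0.01) -> list[float]:
    """Locate isosbestic points in a family of absorbance spectra.

    At an isosbestic wavelength every member of an interconverting family has
    the same absorbance, so the across-series spread vanishes. This scans the
    relative spread sd(A)/mean(A) along the common axis and returns the local
    minima that fall below ``tolerance`` while their flanking neighborhoods
    exceed it. Positions where the mean absorbance is below 1% of its maximum
    are ignored (band wings carry no isosbestic information). A family with
    no spread anywhere significant (identical spectra) is degenerate: a
    warning is emitted and the list is empty.
    """
    series = list(series)
    if len(series) < 3:
        raise DataError("need >= 3 spectra to locate isosbestic points")
    if any(s.signal_kind != ABSORBANCE for s in series):
        raise DataError("isosbestic detection expects absorbance spectra")
    axis, matrix = resample_to_common_axis(series)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    denom = np.where(np.abs(mean) > 1e-12, np.abs(mean), 1e-12)
    spread = sd / denom
    significant = np.abs(mean) > 0.01 * np.abs(mean).max()
    spread = np.where(significant, spread, np.inf)
    below = spread < tolerance
    if below[significant].all():
        warnings.warn("degenerate series: spectra identical within tolerance "
                      "everywhere", stacklevel=2)
        return []
    points: list[float] = []
    # contiguous below-tolerance runs, each flanked by above-tolerance spread
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return points
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        lo, hi = run[0], run[-1]
        left_ok = lo == 0 or spread[lo - 1] >= tolerance
        right_ok = hi == len(spread) - 1 or spread[hi + 1] >= tolerance
        if left_ok and right_ok and not (lo == 0 and hi == len(spread) - 1):
            j = run[int(np.argmin(spread[lo:hi + 1]))]
            points.append(float(axis[j]))
    return points
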