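"""Exception hierarchy.

CLI exit-code mapping: ConfigError -> 2, DataError -> 3, FitError -> 4.
"""


class EsptoolsError(Exception):
    """Base class for all package errors."""


class ConfigError(EsptoolsError):
    """Invalid or incomplete configuration (unknown keys, missing parameters)."""


class DataError(EsptoolsError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """File could not be parsed; message carries file name and line number."""


class AxisAlignmentError(DataError):
    """Spectra in a series do not share (or cannot be interpolated onto) a common axis."""


class FitError(EsptoolsError):
    """A model fit failed or did not converge."""


class UnidentifiableError(FitError):
    """The parameter is not determined by the data (e.g. transition outside the pH window)."""


class SingularityError(FitError):
    """The linear subproblem is rank-deficient (e.g. no spectral change across the series)."""


class DegenerateDesignError(FitError):
    """Regression design has no usable variation (too few points or zero spread)."""
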