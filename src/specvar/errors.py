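"""Exception hierarchy for specvar.

All package-specific failures derive from :class:`SpecvarError` so callers can
catch one type at pipeline boundaries while still distinguishing causes.
"""


class SpecvarError(Exception):
    """Base class for all specvar errors."""


class FormatError(SpecvarError):
    """Malformed input table: unknown condition labels, missing columns."""


class GridError(SpecvarError):
    """Wavelength grid is non-monotone, gapped, or inconsistent."""


class OutOfProtocolError(SpecvarError):
    """Timestamp outside the 07:00-20:00 measurement protocol."""


class DesignError(SpecvarError):
    """Statistical design invalid: too few levels, rank deficiency, empty subset."""


class DegenerateBackgroundError(SpecvarError):
    """White and black background means coincide; reflectance undefined."""


class InsufficientDataError(SpecvarError):
    """Too few retained scans or samples for the requested computation."""


class ParameterError(SpecvarError):
    """Invalid algorithm parameter (e.g. LOF neighbour count >= sample count)."""


class ConsistencyError(SpecvarError):
    """Cross-references between tables do not resolve (unknown scan, sample)."""


class ClassificationError(SpecvarError):
    """Scan shape classification undefined (zero red-edge denominator)."""


class ConvergenceError(SpecvarError):
    """Iterative fit failed to converge; carries optimizer trace in args."""
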