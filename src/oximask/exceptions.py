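"""Exception hierarchy for oximask."""


class OximaskError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OximaskError, ValueError):
    """A value lies outside the mathematical domain of an operation
    (e.g. a non-positive sensor count fed to a log ratio)."""


class ValidationError(OximaskError, ValueError):
    """Structurally invalid input: mismatched shapes, foreign class
    labels, missing columns, inconsistent sample sizes."""


class FitError(OximaskError, RuntimeError):
    """Model fitting failed (singular pooled covariance, degenerate
    class geometry)."""


class DegenerateBoundaryError(FitError):
    """The two classes have coincident means: no discriminant
    direction exists."""


class UnsupportedGeometryError(FitError):
    """The fitted boundary is (numerically) vertical and cannot be
    expressed in Y = slope*X + intercept form."""
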