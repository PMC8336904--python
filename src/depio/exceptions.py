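"""Exception hierarchy for depio."""


class DepioError(Exception):
    """Base class for all depio errors."""


class ValidationError(DepioError, ValueError):
    """Input data violates a structural contract."""


class DimensionError(ValidationError):
    """Array shapes or sector lists do not match."""


class BasisError(ValidationError):
    """Operation applied to a vector in the wrong price basis."""


class DoubleConversionError(BasisError):
    """Purchaser-to-producer conversion applied twice."""


class NonProductiveError(DepioError, ArithmeticError):
    """Coefficient matrix is not productive (spectral radius >= 1)."""


class SingularSystemError(DepioError, ArithmeticError):
    """Extended system matrix is singular or numerically unusable."""


class InfeasibleConfigError(ValidationError):
    """Synthetic-data configuration cannot produce a valid economy."""
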