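"""Exception hierarchy shared across the package."""


class TcrdivError(Exception):
    """Base class for all package errors."""


class FormatError(TcrdivError):
    """An input file violates the expected schema or a table invariant."""


class EmptyInputError(TcrdivError):
    """An operation received an empty table or vector."""


class FeasibilityError(TcrdivError):
    """A target (S, D, S_k) triple cannot be realised by any clone table."""


class ConfigError(TcrdivError):
    """Simulation or pipeline configuration is inconsistent."""


class CollinearityError(TcrdivError):
    """The regression design matrix is rank deficient."""


class DegenerateInputError(TcrdivError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class InsufficientDataError(TcrdivError):
    """Too few observations for the requested estimate."""


class OverSubtractionError(TcrdivError):
    """Measurement error exceeds the model residual: quadrature subtraction undefined."""
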