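"""Exception hierarchy shared across the package."""


class TsallissegError(Exception):
    """Base class for all package-specific errors."""


class InputError(TsallissegError, ValueError):
    """Raised when raw input data violates a precondition (NaN/Inf, bad file)."""


class FormatError(InputError):
    """Raised when a file cannot be read in a supported image format."""


class ContractError(TsallissegError, ValueError):
    """Raised when arguments violate an operation's contract (shape/range)."""


class ParameterError(TsallissegError, ValueError):
    """Raised for invalid algorithm parameters (e.g. non-positive q)."""


class NoThresholdError(TsallissegError, RuntimeError):
    """Raised when no admissible threshold exists (e.g. constant image)."""


class SpecError(TsallissegError, ValueError):
    """Raised when a synthetic-data specification is internally inconsistent."""


class StatisticsError(TsallissegError, ValueError):
    """Raised when a statistic is requested on empty or all-invalid data."""


class ValidationError(TsallissegError, ValueError):
    """Raised when cohort records are mutually inconsistent."""
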