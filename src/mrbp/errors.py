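"""Exception hierarchy used across the package."""


class MrbpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MrbpError):
    """A configuration problem: missing column, unknown label, bad threshold."""


class DataError(MrbpError):
    """Invalid input data: malformed rows, inconsistent LD matrix."""


class EstimationError(MrbpError):
    """An estimator was called on an input it cannot handle (e.g. no instruments)."""


class DomainError(MrbpError, ValueError):
    """An argument outside the mathematical domain of a formula."""
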