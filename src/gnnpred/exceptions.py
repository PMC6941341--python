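"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format problems exit with 2,
capacity problems (similarity-network edge explosion) with 3.
"""


class GnnpredError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GnnpredError):
    """A file could not be parsed as the expected dialect."""


class ValidationError(GnnpredError):
    """Parsed data violates a structural invariant."""


class ConfigError(GnnpredError):
    """A configuration is internally inconsistent or infeasible."""


class CapacityError(GnnpredError):
    """A network would exceed its edge capacity; retry with a higher identity threshold."""


class EmptyNetworkError(GnnpredError):
    """No usable neighborhoods: a neighborhood network cannot be built."""


class DegenerateInputError(ValueError, GnnpredError):
    """Numerically degenerate input (e.g. all counts zero)."""
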