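"""Exception hierarchy.

Every stage raises a subclass of :class:`PestwarnError`, so pipeline callers
can catch one type; the message always names the offending column, cell or
parameter.
"""


class PestwarnError(ValueError):
    """Base class for all package errors."""


class ConfigError(PestwarnError):
    """A configuration object violates one of its invariants."""


class InputError(PestwarnError):
    """Malformed or inconsistent data passed to an operation."""


class DegenerateInputError(PestwarnError):
    """Input is structurally valid but degenerate for the requested operation
    (duplicate interpolation nodes, fewer distinct values than clusters,
    a constant column where variance is required, ...)."""


class InsufficientDataError(PestwarnError):
    """Too few usable observations to carry out the operation."""
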