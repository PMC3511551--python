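"""Typed errors raised across the package.

Degenerate inputs (constant vectors, all-tied ranks) raise
:class:`DegenerateInputError` rather than returning NaN so that genome-wide
drivers can skip and log the offending gene.
"""


class CoexnetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CoexnetError, ValueError):
    """Input violates a precondition (non-finite values, n too small, ...)."""


class DegenerateInputError(CoexnetError, ValueError):
    """Input is formally valid but the statistic is undefined on it."""


class ConfigurationError(CoexnetError, ValueError):
    """Parameters are inconsistent with each other or with the inputs."""


class GeneLookupError(CoexnetError, KeyError):
    """A requested gene id is absent from the expression matrix."""


class EmptyNetworkError(CoexnetError, ValueError):
    """The coordination matrix has no nonzero entry."""


class SliceError(CoexnetError, ValueError):
    """A ranked pair list is too short for the requested slice."""


class ParseError(CoexnetError, ValueError):
    """A flat file could not be parsed; the message names the offending line."""
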