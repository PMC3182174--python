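"""Exception types shared across the package."""


class FatbodyError(Exception):
    """Base class for package errors."""


class ConfigurationError(FatbodyError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class EmptySampleError(FatbodyError, ValueError):
    """A sample column has a zero total and cannot be normalized."""


class InsufficientDataError(FatbodyError, ValueError):
    """Too few observations for the requested test."""


class DomainError(FatbodyError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class GraphConnectivityError(FatbodyError, ValueError):
    """The comparison graph does not connect every sample to a reference."""
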