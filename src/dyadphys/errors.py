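"""Exception hierarchy shared across the package."""


class DyadphysError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DyadphysError, ValueError):
    """A configuration value is invalid; the message names the field."""


class DataError(DyadphysError, ValueError):
    """Input data violate a structural requirement (lengths, finiteness...)."""


class InsufficientDataError(DataError):
    """Not enough samples/beats/crossings to compute the requested quantity."""


class ProtocolError(DyadphysError, ValueError):
    """A request is inconsistent with the experimental protocol
    (e.g. partner/collaboration ratings in the individual condition)."""


class FitError(DyadphysError, ValueError):
    """Model fitting failed (e.g. a class with fewer than 2 samples)."""
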