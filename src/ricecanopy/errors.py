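"""Exception hierarchy.

All package errors derive from :class:`RiceCanopyError` so callers can catch
one base class; the subclasses mirror the failure modes of the public API
(invalid biological/geometric parameters, bad configuration, malformed files,
lifecycle misuse).
"""


class RiceCanopyError(Exception):
    """Base class for all errors raised by ricecanopy."""


class DomainError(RiceCanopyError, ValueError):
    """A physical or geometric parameter is outside its valid domain."""


class ConfigError(RiceCanopyError, ValueError):
    """A configuration value (resolution, algorithm id, layout) is invalid."""


class FormatError(RiceCanopyError, ValueError):
    """A file or in-memory table does not match the expected format."""


class ValidationError(RiceCanopyError, ValueError):
    """A manifest or record fails cross-field validation."""


class StratificationError(RiceCanopyError, ValueError):
    """A stratified split cannot be honoured (some stratum too small)."""


class StateError(RiceCanopyError, RuntimeError):
    """An operation was called on an object in the wrong lifecycle state."""


class NamingError(RiceCanopyError, ValueError):
    """A feature/group name does not follow the expected convention."""
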