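"""Exception hierarchy shared across the package.

All user-facing errors derive from :class:`EdgeGanError` so the CLI can map
them to exit code 1 while genuine bugs surface as exit code 2.
"""


class EdgeGanError(Exception):
    """Base class for all errors raised by edgegan."""


class InvalidArgumentError(EdgeGanError, ValueError):
    """An argument violates a documented precondition."""


class ConflictError(EdgeGanError):
    """An operation would overwrite or duplicate existing state."""


class NotFoundError(EdgeGanError, KeyError):
    """A referenced entity (class label, file) does not exist."""


class StateError(EdgeGanError):
    """An operation was invoked on an object in an unusable state."""


class RegistryFormatError(EdgeGanError):
    """An on-disk model registry is corrupt or version-incompatible."""
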