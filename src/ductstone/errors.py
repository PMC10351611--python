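"""Exception types shared across the package."""


class DuctstoneError(Exception):
    """Base class for package errors."""


class ConfigError(DuctstoneError, ValueError):
    """An invalid configuration value."""


class ValidationError(DuctstoneError, ValueError):
    """Input data violating a documented invariant."""


class ImageIOError(DuctstoneError, IOError):
    """A file could not be read or written."""
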