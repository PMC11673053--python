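"""Exception types shared across the package."""


class PhotoperantError(Exception):
    """Base class for package errors."""


class ConfigurationError(PhotoperantError):
    """Raised when a task, agent, or generator configuration is inconsistent."""


class FormatError(PhotoperantError):
    """Raised when an on-disk file does not conform to the expected layout."""
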