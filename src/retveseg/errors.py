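"""Exception hierarchy shared across the package."""


class RetvesegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RetvesegError):
    """A file decoded, but not to something this package accepts."""


class ConfigError(RetvesegError):
    """An unknown configuration key or an out-of-range value."""


class EmptyFovError(RetvesegError):
    """No field-of-view could be found (e.g. an all-dark image)."""


class EmptyEvaluationError(RetvesegError):
    """An evaluation was requested over zero pixels."""
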