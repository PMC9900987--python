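"""Exception hierarchy shared across the pipeline."""


class ScmstError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScmstError, ValueError):
    """Invalid simulation or run configuration."""


class ValidationError(ScmstError, ValueError):
    """An input violates a documented precondition."""


class InsufficientDataError(ScmstError, ValueError):
    """Too few observations for the requested estimate."""


class FormatError(ScmstError, ValueError):
    """A file on disk does not match the expected schema."""


class DecodingError(ScmstError, KeyError):
    """A (round, channel) pair has no codebook entry."""


class ConsistencyError(ScmstError, ValueError):
    """Two artifacts that must agree (e.g. spots vs codebook) do not."""
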