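"""Exception types shared across the pipeline stages."""


class NeuroloadError(Exception):
    """Base class for all package errors."""


class FormatError(NeuroloadError, ValueError):
    """Malformed file header or unparseable record structure."""


class SamplingError(NeuroloadError, ValueError):
    """Time base inconsistent with a uniform sampling rate."""


class EmptyInputError(NeuroloadError, ValueError):
    """Zero-length or otherwise degenerate input where data is required."""


class EmptySelectionError(NeuroloadError, ValueError):
    """A phase/label selection matched no epochs."""


class PreconditionError(NeuroloadError, ValueError):
    """An operation's documented precondition is violated."""


class ConfigError(NeuroloadError, ValueError):
    """Invalid or inconsistent configuration values."""


class InputTooShortError(NeuroloadError, ValueError):
    """Signal shorter than the filter/transform it should support."""
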