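"""Exception hierarchy shared across the pipeline."""


class GpcompError(Exception):
    """Base class for all package errors."""


class InputError(GpcompError):
    """Unreadable, malformed, or out-of-range input data."""


class EmptyDataError(GpcompError):
    """An operation produced or received an empty dataset."""


class ConfigurationError(GpcompError):
    """Invalid configuration values (sizes, ranges, missing keys)."""


class ConsistencyError(GpcompError):
    """Artifacts that should agree (shapes, orders, checksums) do not."""


class NumericalError(GpcompError):
    """Non-finite loss, divergent sampler, or singular system."""
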