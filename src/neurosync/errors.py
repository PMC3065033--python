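"""Exception hierarchy shared across the package.

The CLI maps each class to a distinct exit code, so computational errors,
malformed inputs and bad configuration stay distinguishable in scripts.
"""


class NeurosyncError(Exception):
    """Base class for all package errors."""


class ConfigError(NeurosyncError):
    """Invalid run configuration or parameter combination."""


class InputFormatError(NeurosyncError):
    """Malformed input file (matrix, montage, time series)."""


class ComputationError(NeurosyncError):
    """A numerical procedure could not be carried out on the given data."""
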