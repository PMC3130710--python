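"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class PolyomicError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PolyomicError):
    """Invalid configuration: bad parameter values, unknown keys, singular matrices."""


class DataError(PolyomicError):
    """Invalid or degenerate data: empty inputs, inconsistent counts, missing groups."""
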