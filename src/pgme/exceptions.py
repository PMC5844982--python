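"""Exception hierarchy shared across the pipeline.

Configuration problems and data problems are distinguished so the CLI can
map them to distinct exit codes (2 and 3 respectively).
"""


class PGMEError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PGMEError):
    """Invalid parameter values, axis mappings or config files."""


class DataError(PGMEError):
    """Unreadable, non-finite or otherwise malformed input data."""


class DegenerateInputError(DataError):
    """Signal too featureless for the requested operation
    (e.g. constant channel, no extrema, no gait cycles)."""
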