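"""Exception hierarchy shared across the pipeline.

Configuration errors (bad thresholds, impossible settings) are kept distinct
from data errors (invalid values in inputs) and consistency errors (tables
that do not agree with each other) so the CLI can map them to exit codes.
"""


class VitiseqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VitiseqError, ValueError):
    """A parameter or configuration value is invalid or self-contradictory."""


class DataError(VitiseqError, ValueError):
    """An input value is outside its legal domain."""


class ConsistencyError(VitiseqError, ValueError):
    """Two inputs that must agree (e.g. candidates vs. reads) do not."""


class InsufficientDataError(VitiseqError, ValueError):
    """Too few observations to compute the requested statistic."""
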