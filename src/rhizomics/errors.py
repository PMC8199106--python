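"""Exception hierarchy.

``ConfigError`` covers bad user configuration (unknown labels, invalid
thresholds, malformed specs); ``DataError`` covers defective input data
(parse failures, broken invariants).  The CLI maps them to distinct exit
codes.
"""


class RhizomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(RhizomicsError):
    """Invalid configuration or parameters."""


class DataError(RhizomicsError):
    """Invalid or inconsistent input data."""
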