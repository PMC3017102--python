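"""Exception hierarchy.

Three error families map onto distinct CLI exit codes: bad configuration
(exit 2), malformed or inconsistent input data (exit 3), and statistics that
are undefined on the given input, e.g. a zero-variance pair vector (exit 4).
"""


class NeuromantelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeuromantelError):
    """Invalid configuration values (counts, fractions, file layout)."""

    exit_code = 2


class DataError(NeuromantelError):
    """Inconsistent or malformed input data (unknown ids, duplicates)."""

    exit_code = 3


class StatisticError(NeuromantelError):
    """A requested statistic is undefined on the given input."""

    exit_code = 4
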