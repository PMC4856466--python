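"""Exception hierarchy.

Configuration problems (bad thresholds, invalid simulation proportions)
are distinguished from data problems (malformed tables, empty inputs) so
the command-line layer can map them to distinct exit codes.
"""


class ParalogDoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ParalogDoseError):
    """Invalid configuration: thresholds, proportions, paths, windows."""


class DataError(ParalogDoseError):
    """Invalid or inconsistent input data."""


class OffsetRangeWarning(UserWarning):
    """The computed RPKM offset falls outside the usual 0.2-0.3 range."""
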