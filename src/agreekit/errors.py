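"""Exception hierarchy.

Input problems (unreadable files, missing columns, too few subjects) and
degenerate statistics (zero variance, undefined slopes) are kept distinct so
the CLI can map them to different exit codes.
"""


class AgreeKitError(Exception):
    """Base class for all package errors."""


class SchemaError(AgreeKitError):
    """A declared column is missing or the column mapping is invalid."""


class InsufficientDataError(AgreeKitError):
    """Fewer than three complete subjects; the regressions are undefined."""


class DegenerateDataError(AgreeKitError):
    """A statistic is undefined on this data (zero variance, no association)."""
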