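"""Exception hierarchy.

Estimation failures are deliberately loud: an empty risk set or an NA
subgroup yields an exception identifying what was undefined, never a
silent zero.
"""


class EquimortError(Exception):
    """Base class for all package errors."""


class ConfigError(EquimortError, ValueError):
    """Invalid configuration; message names the offending field."""


class UndefinedEstimateError(EquimortError):
    """A mortality estimate could not be formed (e.g. empty risk set)."""


class UnsupportedMeasureError(EquimortError):
    """Measure not defined for this dimension kind (e.g. ACI on binary)."""


class UndefinedMeasureError(EquimortError):
    """Measure undefined on this table (NA subgroup, zero denominator...)."""


class TableParseError(EquimortError, ValueError):
    """Malformed disaggregated-table CSV; message carries the row number."""
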