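"""Exception hierarchy.

All package errors derive from :class:`InflaError` so callers can catch one
base class at pipeline boundaries.
"""


class InflaError(Exception):
    """Base class for all package errors."""


class ConfigError(InflaError):
    """Invalid configuration value (bad fraction, non-positive scale, ...)."""


class DataError(InflaError):
    """Input data violate a precondition (empty table, bad dates, ...)."""


class BinningError(DataError):
    """Quantile binning impossible (degenerate or insufficient values)."""


class FitError(InflaError):
    """A statistical fit could not be produced (non-convergence, no events)."""
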