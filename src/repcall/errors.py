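"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`RepcallError`, so callers (and the CLI) can distinguish defined
failure modes from bugs.
"""


class RepcallError(Exception):
    """Base class for all errors raised by repcall."""


class ConfigError(RepcallError):
    """Invalid or missing configuration (assay preset, YAML, columns)."""


class CohortParseError(RepcallError):
    """A cohort file row could not be parsed; message names the row."""


class ValidationError(RepcallError):
    """Well-formed input that violates a domain invariant."""


class EstimationError(RepcallError):
    """A performance statistic cannot be estimated (empty denominator)."""


class DegenerateTableError(RepcallError):
    """A 2x2 table with a zero row or column margin."""


class UnreachableTargetError(RepcallError):
    """A requested ROC operating point lies beyond the censored curve."""


class CalibrationError(RepcallError):
    """The shipped simulation preset misses its calibration targets."""
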