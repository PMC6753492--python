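"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 2, everything else
derived from SpikecalError -> 3.
"""


class SpikecalError(Exception):
    """Base class for all package errors."""


class ValidationError(SpikecalError, ValueError):
    """Invalid user input: bad config values, malformed files, bad arguments."""


class CalibrationError(SpikecalError):
    """Calibration cannot be computed (zero totals, no usable spike genes...)."""


class SizingError(ValidationError):
    """Requested synthetic layout does not fit on the toy contig."""


class ComputationError(SpikecalError):
    """A downstream computation failed on otherwise valid input."""


class PipelineError(SpikecalError):
    """A pipeline stage failed; message carries the stage name and cause."""
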