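"""Exception hierarchy shared across the pipeline.

Error classes map onto the CLI exit-code contract: configuration problems
(bad parameters, malformed rule files) exit 2, data problems (unusable
streams, insufficient steps) exit 3.
"""


class BalanceMocapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BalanceMocapError):
    """Invalid parameter value or malformed configuration file."""


class FormatError(BalanceMocapError):
    """Malformed input data (non-monotone timestamps, length mismatch...)."""


class UnusableStreamError(BalanceMocapError):
    """A stream too short or too broken to repair."""


class AlignmentError(BalanceMocapError):
    """Streams share no usable temporal overlap."""


class DegenerateGravityError(BalanceMocapError):
    """Accelerometer norm is zero over a whole window; attitude unobservable."""


class InsufficientDataError(BalanceMocapError):
    """Too few retained samples for a statistic to be meaningful."""


class InsufficientStepsError(BalanceMocapError):
    """Fewer complete strides than the gait parameters require."""


class DegenerateTargetError(BalanceMocapError):
    """A motor-score analytic has target equal to baseline."""
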