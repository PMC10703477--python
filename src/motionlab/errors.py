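"""Exception hierarchy.

Validation/contract problems (bad parameters, broken preconditions) raise
:class:`ValidationError` subclasses and map to CLI exit code 2; file-format
problems raise :class:`FileFormatError`; genuine I/O failures propagate the
builtin :class:`OSError` and map to exit code 1.
"""


class MotionLabError(Exception):
    """Base class for all library errors."""


class ValidationError(MotionLabError, ValueError):
    """A parameter or input violates an operation's contract."""


class TimeBaseError(ValidationError):
    """Time arrays that must agree do not."""


class ContractError(ValidationError):
    """An object is used in a way its provenance forbids.

    Example: feeding a display-only downsampled element into kinematics,
    or calling a uniform-sampling operation on a ragged trace.
    """


class OrderingError(ValidationError):
    """Gait events out of the required order."""


class DetectionError(MotionLabError):
    """Automatic event detection found no candidates."""


class FileFormatError(MotionLabError):
    """A file exists and is readable but its content is malformed."""
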