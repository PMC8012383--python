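"""Exception hierarchy for the howl-identification pipeline."""


class HowlIdError(Exception):
    """Base class for all package errors."""


class ContourParseError(HowlIdError):
    """A contour file contains a row that cannot be parsed."""


class DegenerateContourError(HowlIdError):
    """A contour is too short to carry any information (fewer than two points,
    or shorter than one resampling step)."""


class ContourValidationError(HowlIdError):
    """A contour violates a structural invariant (non-increasing times,
    non-positive frequencies, mismatched lengths)."""


class SchemaError(HowlIdError):
    """A table or score matrix is missing required columns, or its columns do
    not match the model it is being fed to."""
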