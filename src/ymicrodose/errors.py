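"""Exception types shared across the package."""


class YMicrodoseError(Exception):
    """Base class for package errors."""


class InvalidParameterError(YMicrodoseError, ValueError):
    """A parameter violates a precondition (wrong sign, range, shape...)."""


class CapacityError(YMicrodoseError):
    """Requested sphere packing cannot be realized in the field of view."""


class FormatError(YMicrodoseError, ValueError):
    """An input file does not conform to the expected format."""


class DegenerateDataError(YMicrodoseError, ValueError):
    """A statistic is undefined on the given data (constant input, all-zero
    differences, one-sided split...)."""
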