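"""Exception types shared across the package."""


class LequantError(Exception):
    """Base class for package errors."""


class FormatError(LequantError):
    """A file did not conform to the expected dialect (missing field, bad header)."""


class ParameterError(LequantError, ValueError):
    """An argument value is outside its admissible range."""


class DataError(LequantError, ValueError):
    """Input data violate an invariant (e.g. non-positive precision)."""
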