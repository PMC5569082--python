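"""Exception hierarchy shared across the pipeline."""


class PTOCTError(Exception):
    """Base class for all package errors."""


class ParameterError(PTOCTError, ValueError):
    """A physical or algorithmic parameter violates its constraints."""


class ValidationError(PTOCTError, ValueError):
    """A data container violates one of its invariants."""


class FormatError(PTOCTError, IOError):
    """A file does not follow the expected on-disk layout."""


class DimensionError(PTOCTError, ValueError):
    """Arrays that must be congruent have mismatched shapes."""
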