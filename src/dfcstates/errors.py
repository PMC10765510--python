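"""Exception hierarchy shared across the pipeline."""


class DfcError(Exception):
    """Base class for all package errors."""


class LoadError(DfcError):
    """A file could not be parsed into a valid input (missing or non-numeric cells)."""


class SchemaError(DfcError):
    """An input violates a structural invariant (shapes, duplicates, labels)."""


class DegenerateInputError(DfcError):
    """Input is numerically degenerate for the requested operation (e.g. zero-variance ROI)."""


class InputTooShortError(DfcError):
    """Time series shorter than one window."""


class GenerationError(DfcError):
    """Synthetic-data construction failed (e.g. covariance not positive definite)."""


class MappingError(DfcError):
    """An ROI has no lobe assignment."""
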