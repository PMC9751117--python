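"""Exception hierarchy shared across the package."""


class Seq2ExpError(Exception):
    """Base class for all package errors."""


class ValidationError(Seq2ExpError, ValueError):
    """Malformed input: bad alphabet, ragged lengths, out-of-range coordinates."""


class FrameError(ValidationError):
    """Sequence length incompatible with the codon reading frame."""


class ConfigurationError(Seq2ExpError, ValueError):
    """Inconsistent or incomplete configuration (unknown property, empty grid, ...)."""


class SizingError(Seq2ExpError, ValueError):
    """A requested sample or partition does not fit the available records."""


class CapabilityError(Seq2ExpError, TypeError):
    """Operation not supported by the given model family (e.g. no gradient access)."""


class TrainingError(Seq2ExpError, RuntimeError):
    """Model training diverged or failed."""
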