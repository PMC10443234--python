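"""Exception hierarchy.

Everything raised on purpose derives from :class:`CrossgenError` so callers
can catch package errors without swallowing programming mistakes.
"""


class CrossgenError(Exception):
    """Base class for all errors raised by crossgen."""


class ValidationError(CrossgenError, ValueError):
    """An input violates a documented precondition."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested estimator."""


class DimensionError(ValidationError):
    """Mismatched array dimensions (channels, replicates, time axes)."""


class FoldError(CrossgenError, ValueError):
    """A cross-validation fold is degenerate (e.g. missing one class)."""


class NumericalError(CrossgenError, RuntimeError):
    """A linear-algebra step failed; usually cured by nonzero shrinkage."""


class CalibrationError(CrossgenError, RuntimeError):
    """Signal-scale calibration could not reach its target."""


class DegenerateSampleError(CrossgenError, ValueError):
    """A statistical test received a sample with zero variance."""


class CapacityError(ValidationError):
    """A cortical area holds fewer sources than requested."""


class FormatError(CrossgenError, ValueError):
    """An on-disk container is malformed; the message names the field."""


class ConfigError(CrossgenError, ValueError):
    """A configuration document is invalid; the message names the key."""


class ManifestError(CrossgenError, RuntimeError):
    """Output manifest already exists, or checksum verification failed."""
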