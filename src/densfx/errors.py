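"""Exception hierarchy shared across the pipeline."""


class DensfxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DensfxError):
    """A file could not be parsed as the expected format."""


class DimensionError(DensfxError):
    """An array has the wrong dimensionality or mismatched shapes."""


class ValidationError(DensfxError):
    """Data violates a domain-type invariant (e.g. non-binary mask)."""


class ParameterError(DensfxError, ValueError):
    """A parameter is outside its admissible range."""


class DegenerateInputError(DensfxError):
    """Input is formally valid but degenerate for the operation
    (constant volume for z-scoring, constant region for a percentile window,
    texture ROI with no co-occurring pairs, absent class for a rate)."""


class EmptyROIError(DensfxError):
    """An operation requiring a non-empty mask received an empty one."""


class FeasibilityError(DensfxError):
    """Requested target cannot be reached in the chosen mode; the message
    reports the achievable range."""


class AugmentationError(DensfxError):
    """A random augmentation constraint could not be satisfied."""


class TrainingError(DensfxError):
    """Optimization diverged (non-finite loss); carries the epoch index."""


class SplitError(DensfxError):
    """A dataset split would leave a partition empty."""


class SchemaError(DensfxError):
    """Feature table does not match the schema a model was fitted with."""
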