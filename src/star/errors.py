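"""Exception hierarchy shared across the package."""


class StarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StarError):
    """An input table is missing required columns or has an unusable layout."""


class EventValidationError(StarError):
    """An event record violates ordering, bounds, or sipper-alternation rules."""


class DegenerateFitError(StarError):
    """A regression cannot be fit (too few points or constant predictor)."""


class DegenerateCohortError(StarError):
    """Cohort-mean normalization is undefined (zero mean or single subject)."""


class CombinatorialBoundError(StarError):
    """Exhaustive subset enumeration would exceed the configured bound."""
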