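"""Exception hierarchy for the aspos package."""


class AsposError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AsposError, ValueError):
    """An argument violates a precondition (range, emptiness, shape)."""


class DegenerateAssessmentError(AsposError):
    """An assessment carries no assessable items, so no total exists."""


class UndefinedStatisticError(AsposError):
    """The requested statistic is undefined on this input
    (zero variance, constant column, degenerate marginals)."""


class ConfigurationError(AsposError, ValueError):
    """Simulation or pipeline parameters are inconsistent."""


class InsufficientRatersError(AsposError):
    """Fewer raters available than the operation requires."""


class PipelineError(AsposError):
    """A stage of the full validation run failed; names the stage and cause."""


class ParseError(AsposError, ValueError):
    """A data file violates the expected schema.

    Carries human-readable context (row numbers, field names) in the
    message so malformed clinical exports can be located quickly.
    """
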