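"""Typed errors raised across the pipeline.

Every failure mode that a caller can act on gets its own class; silent NaN
propagation is never used for degenerate inputs.
"""


class ScreendxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScreendxError):
    """Invalid simulation or design configuration (probability out of range, ...)."""


class SchemaError(ScreendxError):
    """Cohort CSV violates the canonical schema or a record-level invariant."""


class SamplingError(ScreendxError):
    """Two-phase sample cannot be drawn or weighted (empty population/stratum)."""


class EstimationError(ScreendxError):
    """Accuracy/ROC estimate undefined (empty margin, no cases, singular design)."""


class BootstrapError(ScreendxError):
    """Bootstrap resampling failed on too many replicates."""


class MissingDataError(ScreendxError):
    """Imputation or response-model fitting cannot proceed."""


class PipelineError(ScreendxError):
    """A pipeline stage failed; message names the stage and counts processed."""
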