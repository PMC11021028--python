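"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PipelineError` so callers can trap
pipeline failures without catching unrelated bugs.  Most exceptions carry the
offending identifiers (gene, marker, strain, column) in their message.
"""


class PipelineError(Exception):
    """Base class for all mpp-eqtl errors."""


class InvalidArgumentError(PipelineError, ValueError):
    """A parameter violates a documented precondition."""


class InvalidReferenceError(PipelineError, KeyError):
    """An identifier refers to an object that does not exist (gene, marker...)."""


class ValidationError(PipelineError, ValueError):
    """An on-disk or in-memory object violates a structural invariant."""


class RankDeficiencyError(PipelineError, ValueError):
    """A design matrix is rank deficient; message names the confounded columns."""


class AlignmentError(PipelineError, ValueError):
    """Two objects that must share an index (strains, genes) do not."""


class MissingPairError(PipelineError, ValueError):
    """Response construction found strains lacking one of the two treatments."""


class DegenerateInputError(PipelineError, ValueError):
    """Input has no usable variation (constant matrix, all-zero sample...)."""


class UnderdeterminedModelError(PipelineError, ValueError):
    """Fewer observations than parameters in a regression model."""


class UndefinedCorrelationError(PipelineError, ValueError):
    """Correlation requested between vectors with zero variance."""
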