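"""Exception hierarchy for gliprio.

Every rejected input raises a subclass of :class:`GliprioError` so callers can
distinguish pipeline-logic failures from programming errors.
"""


class GliprioError(Exception):
    """Base class for all gliprio errors."""


class InvalidParameterError(GliprioError, ValueError):
    """A model parameter or threshold is outside its valid range."""


class DegenerateDesignError(GliprioError):
    """The regression design matrix is rank-deficient (e.g. constant exposure)."""


class AlleleMismatchError(GliprioError):
    """A cohort's allele pair cannot be reconciled with the canonical pair."""


class EmptyInputError(GliprioError, ValueError):
    """An operation requiring at least one record received none."""


class InsufficientCohortsError(GliprioError):
    """Fewer cohorts than the operation requires (e.g. heterogeneity needs >= 2)."""


class SingularPrecisionError(GliprioError):
    """A per-cohort covariance matrix is singular; the joint test is undefined."""


class InconsistentAnnotationError(GliprioError):
    """Gene annotation spans multiple chromosomes or is otherwise malformed."""


class InvalidPositionError(GliprioError, ValueError):
    """A genomic position lies outside the declared chromosome bounds."""


class VocabularyError(GliprioError, ValueError):
    """A trait, exposure or ancestry label is outside the closed vocabulary."""


class ConsistencyError(GliprioError):
    """Planted-truth bookkeeping references unknown genes or variants."""
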