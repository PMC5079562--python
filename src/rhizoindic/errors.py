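"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`RhizoindicError` so callers can catch the
package's failures with one clause; the numeric ones also subclass
``ValueError`` to behave like ordinary domain errors.
"""


class RhizoindicError(Exception):
    """Base class for all package errors."""


class DomainError(RhizoindicError, ValueError):
    """A parameter is outside its mathematical domain."""


class EmptySampleError(RhizoindicError, ValueError):
    """An all-zero abundance vector where a positive total is required."""


class InsufficientReadsError(RhizoindicError, ValueError):
    """A subsampling depth exceeds the reads available in the sample."""


class InsufficientDataError(RhizoindicError, ValueError):
    """Too few records/samples for the requested aggregation."""


class DegenerateCurveError(RhizoindicError, ValueError):
    """A rarefaction curve whose final value is not positive."""


class UndefinedCoverageError(RhizoindicError, ValueError):
    """ACE sample coverage is zero (every rare individual is a singleton)."""


class DegenerateTableError(RhizoindicError, ValueError):
    """A contingency table with a zero marginal total."""


class EmptySelectionError(RhizoindicError, ValueError):
    """A filter removed every sample or taxon."""


class LookupError_(RhizoindicError, KeyError):
    """A sample or taxon named in a manifest is missing from the tables."""
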