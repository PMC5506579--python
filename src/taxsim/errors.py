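"""Exception hierarchy shared across the package."""


class TaxsimError(Exception):
    """Base class for all package-specific errors."""


class TaxonomyError(TaxsimError):
    """A taxonomy document violates a structural invariant."""


class CycleError(TaxonomyError):
    """The parent relation contains a cycle; the message names one member."""


class DanglingReferenceError(TaxonomyError):
    """A parent id does not resolve to any declared term."""


class AxisPartitionError(TaxonomyError):
    """Axis membership is inconsistent (two axes for one term, edge across
    axes, or an axis without exactly one root)."""


class UnknownTermError(TaxonomyError, KeyError):
    """A term id was looked up that the taxonomy does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return Exception.__str__(self)


class CorpusError(TaxsimError):
    """An annotation document violates a corpus invariant."""


class ValidationError(CorpusError):
    """Annotations reference unknown terms or mis-filed axes."""


class CrossAxisError(TaxsimError):
    """Two annotation sets handed to a per-axis measure span different axes."""


class DegenerateDistributionError(TaxsimError):
    """A baseline distribution has zero variance; the t statistic is undefined."""
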