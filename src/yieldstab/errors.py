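"""Exception hierarchy for yieldstab.

All package errors derive from :class:`YieldStabError` so callers can catch
one base class; subclasses distinguish schema problems (bad input files) from
computation problems (undefined statistics).
"""


class YieldStabError(Exception):
    """Base class for all yieldstab errors."""


class SchemaError(YieldStabError):
    """An input table is missing a mandatory column or declares an unknown factor."""


class ParseError(YieldStabError):
    """A cell could not be parsed (e.g. non-numeric yield); carries the row number."""


class IntegrityError(YieldStabError):
    """Duplicate keys or records violating panel invariants."""


class AlignmentError(YieldStabError):
    """Observed and predicted series share no keys, or treatments mismatch."""


class DomainError(YieldStabError):
    """A statistic is undefined for the given input (e.g. non-positive mean)."""


class StabilityUndefinedError(DomainError):
    """Zero interannual variance: log-variance statistics are not representable."""


class SingularDesignError(DomainError):
    """A regression design matrix is singular (e.g. all log-means identical)."""


class ConcordanceUndefinedError(DomainError):
    """Zero variance in one of the vectors entering a concordance statistic."""


class RangeError(YieldStabError):
    """A parameter range with min >= max."""


class CapabilityError(YieldStabError):
    """Request exceeds what the method supports (e.g. too many design dimensions)."""


class FailureRateError(YieldStabError):
    """Too many failed model runs for a reliable sensitivity estimate."""
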