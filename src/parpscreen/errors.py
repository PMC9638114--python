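"""Exception hierarchy.

All package-specific failures derive from :class:`ParpScreenError` so callers
can catch one base class at pipeline boundaries; subclasses distinguish
format/schema problems (bad files) from domain problems (bad values) and
selection/pairing problems (bad queries).
"""


class ParpScreenError(Exception):
    """Base class for all errors raised by parpscreen."""


class FormatError(ParpScreenError, ValueError):
    """A file could not be parsed (malformed record, non-numeric field)."""


class SchemaError(FormatError):
    """A table violates its column schema or uniqueness constraints."""


class SelectionError(ParpScreenError, KeyError):
    """A structural selection matched nothing."""


class PairingError(ParpScreenError, ValueError):
    """Two coordinate lists cannot be paired atom-by-atom."""


class InputError(ParpScreenError, ValueError):
    """An operation received empty or inconsistent input."""


class FitError(ParpScreenError, ValueError):
    """A regression design is degenerate (rank-deficient)."""


class MetricError(ParpScreenError, ValueError):
    """A metric is undefined for the given labels (e.g. single-class AUC)."""


class NormalizationError(ParpScreenError, ValueError):
    """A profile cannot be z-scored (zero spread)."""


class DomainError(ParpScreenError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class ActivitySpreadError(ParpScreenError, ValueError):
    """Replicate IC50 values disagree by more than the allowed fold-spread."""
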