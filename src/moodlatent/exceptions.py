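"""Exception hierarchy for moodlatent.

All package-specific failures derive from :class:`MoodLatentError` so callers
can catch one base class at pipeline boundaries.  Validation failures
additionally derive from :class:`ValueError` to play well with numpy/sklearn
conventions.
"""


class MoodLatentError(Exception):
    """Base class for all moodlatent errors."""


class ValidationError(MoodLatentError, ValueError):
    """An input value violates a documented precondition."""


class IncompleteResponseError(ValidationError):
    """A questionnaire response is missing one or more required items."""


class UnsupportedOperationError(MoodLatentError, TypeError):
    """The requested operation is undefined for this instrument (e.g. an
    MZ total score: the six mood items are a vector instrument with no
    published summation rule)."""


class ParseError(MoodLatentError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class EmptyMatrixError(MoodLatentError, ValueError):
    """No complete records survive listwise deletion for the requested
    instrument/cohort slice."""


class InsufficientDataError(MoodLatentError, ValueError):
    """Fewer samples than the estimator requires (e.g. N < 2 for a
    covariance)."""


class DegenerateSampleError(MoodLatentError, ValueError):
    """A sample has too few points or zero variance for density estimation;
    callers may fall back to a point-mass flag."""
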