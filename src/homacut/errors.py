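"""Exception hierarchy shared across the package.

Every error raised by homacut derives from :class:`HomacutError`, so callers
(including the CLI, which maps them to exit code 2) can catch one type.
"""


class HomacutError(Exception):
    """Base class for all homacut errors."""


class InvalidMeasurementError(HomacutError):
    """A physical measurement is missing, non-positive, or otherwise unusable."""


class MissingLabError(HomacutError):
    """A required laboratory value is absent."""


class EmptyCohortError(HomacutError):
    """Exclusion filtering removed every record."""


class IncompleteRecordError(HomacutError):
    """A record lacks an input required by a classification rule."""


class InsufficientDataError(HomacutError):
    """Too few observations for the requested estimator."""


class InvalidArgumentError(HomacutError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(HomacutError):
    """Input is constant or otherwise degenerate for the requested statistic."""


class DegenerateLabelsError(HomacutError):
    """Only one outcome class is present; no ROC curve exists."""


class NoCutpointError(HomacutError):
    """The ROC curve has no finite candidate threshold."""


class NamedColumnError(HomacutError):
    """An input table is missing required, named columns."""
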