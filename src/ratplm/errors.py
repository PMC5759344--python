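"""Exception hierarchy for the ratplm package."""


class RatPLMError(ValueError):
    """Base class for all package errors."""


class FormatError(RatPLMError):
    """A file could not be parsed as the expected format."""


class ConsistencyError(RatPLMError):
    """Components of a recording disagree (e.g. durations mismatch)."""


class ValidationError(RatPLMError):
    """Invalid values passed to an operation (negative times, unsorted events...)."""


class UndefinedMetricError(RatPLMError):
    """A metric has no defined value (zero denominator, no episodes of a stage).

    Raised instead of silently reporting 0, which would be a different claim.
    """
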