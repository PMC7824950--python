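"""Exception hierarchy for survey loading, validation and analysis."""


class SurveyError(Exception):
    """Base class for all package errors."""


class SchemaError(SurveyError):
    """A required column is missing from an input table."""


class IntegrityError(SurveyError):
    """A reference does not resolve, or a uniqueness invariant is broken."""


class VocabularyError(SurveyError):
    """A categorical value is not in the declared closed vocabulary."""


class ParameterError(SurveyError):
    """An operation was called with an invalid argument."""


class ConsistencyError(SurveyError):
    """Counts passed to an index formula violate its preconditions."""


class ConfigError(SurveyError):
    """A synthetic-data or pipeline configuration is infeasible."""


class UndefinedResultError(SurveyError):
    """The requested statistic is undefined for this input (e.g. empty sets)."""


class FittingError(SurveyError):
    """A regression model failed to fit (non-convergence or rank deficiency)."""
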