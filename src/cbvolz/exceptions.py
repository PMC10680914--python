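"""Exception hierarchy for the pipeline.

``SchemaError`` and ``ValidationError`` signal bad input (CLI exit code 2);
``FitError`` and its subclasses signal statistical-stage failures (exit 3).
"""


class CbvolzError(Exception):
    """Base class for all package errors."""


class SchemaError(CbvolzError):
    """An expected column is missing or the column mapping is inconsistent."""


class ValidationError(CbvolzError):
    """Input values violate a hard invariant (duplicate ids, bad cells...)."""


class FitError(CbvolzError):
    """A model fit could not be performed."""


class InsufficientDataError(FitError):
    """Too few records to determine the requested model."""


class GenerationError(CbvolzError):
    """The synthetic-cohort configuration is infeasible."""
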