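"""Exception hierarchy for wearvalid.

All package errors derive from :class:`WearvalidError` so callers can catch
them with one clause; the subclasses distinguish schema problems in input
files, invalid values, and statistical preconditions.
"""


class WearvalidError(Exception):
    """Base class for all errors raised by wearvalid."""


class SchemaError(WearvalidError, ValueError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(WearvalidError, ValueError):
    """A value violates a data-model invariant (e.g. non-positive measurement)."""


class InsufficientDataError(WearvalidError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(WearvalidError, ValueError):
    """Input with zero variance (or otherwise degenerate) where spread is required."""
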