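"""Exception hierarchy shared across the package."""


class MetaError(Exception):
    """Base class for all domain errors raised by forestmeta."""


class InvalidTableError(MetaError):
    """A 2x2 table violates its invariants (negative or out-of-range counts)."""


class DegenerateTableError(MetaError):
    """A zero cell makes the requested effect measure undefined and the
    zero-cell policy is 'error'."""


class NoDataError(MetaError):
    """An operation that needs at least one study received none."""


class HeterogeneityUndefinedError(MetaError):
    """Q / I2 / tau2 need at least two studies."""


class PredictionIntervalUndefinedError(MetaError):
    """The prediction interval needs k >= 3 (t distribution with k-2 df)."""


class InvalidScenarioError(MetaError):
    """A simulation scenario implies risks outside [0, 1] or inconsistent
    field lengths."""


class NotEstimableError(MetaError):
    """A stratified estimator has no eligible events anywhere."""


class NonIdentifiableError(MetaError):
    """The regression design matrix is rank deficient (or separated)."""


class MissingDataError(MetaError):
    """A required column (year, subgroup proportion) is absent."""


class ParseError(MetaError):
    """A delimited input file is malformed; carries row/column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        where = []
        if row is not None:
            where.append(f"row {row}")
        if column is not None:
            where.append(f"column '{column}'")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)
        self.row = row
        self.column = column
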