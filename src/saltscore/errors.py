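"""Exception hierarchy used across the package."""


class SaltScoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SaltScoreError, ValueError):
    """Invalid configuration; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class DomainError(SaltScoreError, ValueError):
    """Input outside the mathematical domain of an operation."""


class CodingError(SaltScoreError, ValueError):
    """A questionnaire response could not be mapped to an ordinal code."""

    def __init__(self, item: str, value, message: str = "unrecognized response"):
        self.item = item
        self.value = value
        super().__init__(f"{message} for item '{item}': {value!r}")


class UndefinedRatioError(DomainError):
    """Sodium-to-potassium ratio requested with zero potassium."""


class SingularDesignError(SaltScoreError, ValueError):
    """Rank-deficient regression design; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular design matrix; collinear columns: " + ", ".join(map(str, self.columns))
        )


class PredictionError(SaltScoreError, KeyError):
    """A prediction equation referenced a variable absent from the record."""

    def __init__(self, variable: str):
        self.variable = variable
        super().__init__(f"record is missing variable '{variable}' required by the equation")


class DegenerateDataError(SaltScoreError, ValueError):
    """Data degenerate for the requested statistic (e.g. zero variance)."""
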