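"""Exception hierarchy shared across the package.

The three branches map onto the CLI exit codes: configuration problems
(exit 2), data problems (exit 3), numerical failures (exit 4).
"""


class QualinearError(Exception):
    """Base class for all package errors."""


class ConfigError(QualinearError):
    """Invalid or inconsistent configuration (bad fractions, unknown columns...)."""


class DataError(QualinearError):
    """Problems with the input data itself."""


class MissingValuesError(DataError):
    """Missing cells found during validation.

    Attributes
    ----------
    counts : dict
        Per-column count of missing cells (only offending columns).
    """

    def __init__(self, counts):
        self.counts = dict(counts)
        cols = ", ".join(f"{k} ({v})" for k, v in self.counts.items())
        super().__init__(f"missing values in column(s): {cols}")


class EmptyDatasetError(DataError):
    """Zero-row input where at least one observation is required."""


class UnseenLevelError(DataError):
    """A category label at transform time that was absent when the encoding was built."""


class NumericalError(QualinearError):
    """Numerical failure during fitting."""


class CollinearityError(NumericalError):
    """Rank-deficient design matrix.

    Attributes
    ----------
    columns : list of str
        Names of the columns implicated in the collinearity.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(self.columns)
        )


class LPInfeasibleError(NumericalError):
    """The spread linear program reported infeasibility (should not occur
    with free intercept spreads)."""


class DivergenceError(NumericalError):
    """Non-finite loss during network training; advise a smaller learning rate."""
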