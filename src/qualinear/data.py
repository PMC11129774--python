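"""Data model, validation, and dummy (indicator) coding of qualitative predictors.

A :class:`Dataset` wraps a :class:`pandas.DataFrame` together with the roles
of its columns: one numeric response, zero or more numeric predictors, and
zero or more categorical predictors.  A categorical variable with ``alpha``
levels enters a linear model through ``alpha - 1`` indicator columns; the
omitted *reference level* is the category whose effect is absorbed by the
intercept, so its rows carry all-zero indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DataError,
    EmptyDatasetError,
    MissingValuesError,
    UnseenLevelError,
)

__all__ = [
    "Dataset",
    "DummyEncoding",
    "validate",
    "encode_dummies",
    "design_matrix",
    "response_function_decomposition",
]


@dataclass(frozen=True)
class Dataset:
    """A rectangular table with declared column roles.

    Parameters
    ----------
    frame : pandas.DataFrame
        The data; must contain every declared column.
    response : str
        Name of the numeric response column.
    numeric : tuple of str
        Names of numeric predictor columns.
    categorical : tuple of str
        Names of categorical predictor columns.
    """

    frame: pd.DataFrame
    response: str
    numeric: tuple = ()
    categorical: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "numeric", tuple(self.numeric))
        object.__setattr__(self, "categorical", tuple(self.categorical))
        declared = [self.response, *self.numeric, *self.categorical]
        missing = [c for c in declared if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"declared column(s) not in data: {', '.join(missing)}")
        dupes = {c for c in declared if declared.count(c) > 1}
        if dupes:
            raise ConfigError(f"column(s) declared in more than one role: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def response_values(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, response, numeric=(), categorical=()) -> "Dataset":
        frame = pd.read_csv(path)
        return cls(frame=frame, response=response, numeric=numeric,
                   categorical=categorical)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def with_frame(self, frame: pd.DataFrame) -> "Dataset":
        """Same roles, different rows (used by resampling)."""
        return replace(self, frame=frame)


def validate(dataset: Dataset) -> Dataset:
    """Check for missing cells and degenerate shapes; return the dataset unchanged.

    Mirrors the usual pre-modelling scan of per-column missing counts.

    Raises
    ------
    EmptyDatasetError
        If the table has zero rows.
    MissingValuesError
        Listing every offending column with its missing count.
    """
    if dataset.n == 0:
        raise EmptyDatasetError("empty dataset")
    counts = dataset.frame.isna().sum()
    bad = counts[counts > 0]
    if len(bad):
        raise MissingValuesError(bad.to_dict())
    return dataset


def missing_counts(dataset: Dataset) -> dict:
    """Per-column missing-cell counts (all zero for a clean table)."""
    return dataset.frame.isna().sum().to_dict()


@dataclass(frozen=True)
class DummyEncoding:
    """Mapping from one categorical variable to its indicator columns.

    ``levels`` is the ordered list of the variable's ``alpha`` categories and
    ``columns`` the ``alpha - 1`` indicator column names (one per
    non-reference level, in order).  The reference level maps to the all-zero
    indicator row.
    """

    variable_name: str
    levels: tuple
    reference_level: str
    columns: tuple = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.reference_level not in self.levels:
            raise ConfigError(
                f"reference level {self.reference_level!r} not among levels "
                f"{list(self.levels)} of {self.variable_name!r}"
            )
        non_ref = tuple(l for l in self.levels if l != self.reference_level)
        object.__setattr__(
            self, "columns",
            tuple(f"{self.variable_name}_{l}" for l in non_ref),
        )

    @property
    def non_reference_levels(self) -> tuple:
        return tuple(l for l in self.levels if l != self.reference_level)

    def transform(self, labels) -> np.ndarray:
        """Indicator matrix (n, alpha-1) for a vector of labels.

        Raises :class:`UnseenLevelError` for any label outside ``levels``.
        """
        labels = np.asarray(labels, dtype=object)
        unseen = sorted(set(labels) - set(self.levels))
        if unseen:
            raise UnseenLevelError(
                f"unseen level(s) {unseen} for variable {self.variable_name!r}"
            )
        out = np.zeros((len(labels), len(self.columns)))
        for j, level in enumerate(self.non_reference_levels):
            out[labels == level, j] = 1.0
        return out

    def decode(self, indicator_row) -> str:
        """Recover the original label from one indicator row."""
        row = np.asarray(indicator_row, dtype=float)
        if row.shape != (len(self.columns),):
            raise DataError(
                f"indicator row has length {row.size}, expected {len(self.columns)}"
            )
        ones = np.flatnonzero(row == 1.0)
        if row.sum() == 0:
            return self.reference_level
        if len(ones) == 1 and set(np.unique(row)) <= {0.0, 1.0}:
            return self.non_reference_levels[ones[0]]
        raise DataError(f"not a valid indicator row: {row.tolist()}")


def encode_dummies(dataset: Dataset, variable_name: str,
                   reference_level: str | None = None):
    """Replace one categorical column by its ``alpha - 1`` indicator columns.

    The default reference level is the last level in lexicographic order, a
    deterministic choice that for treatments labelled A, B, C omits C.

    Returns
    -------
    (Dataset, DummyEncoding)
        A new dataset whose categorical column is replaced by 0/1 numeric
        columns appended to the numeric predictors, and the encoding used.
    """
    if variable_name not in dataset.categorical:
        raise ConfigError(f"{variable_name!r} is not a declared categorical predictor")
    labels = dataset.frame[variable_name]
    levels = tuple(sorted(labels.astype(str).unique()))
    if reference_level is None:
        reference_level = levels[-1]
    enc = DummyEncoding(variable_name=variable_name, levels=levels,
                        reference_level=str(reference_level))
    ind = enc.transform(labels.astype(str).to_numpy())
    frame = dataset.frame.drop(columns=[variable_name]).copy()
    for j, col in enumerate(enc.columns):
        frame[col] = ind[:, j]
    new = Dataset(
        frame=frame,
        response=dataset.response,
        numeric=dataset.numeric + enc.columns,
        categorical=tuple(c for c in dataset.categorical if c != variable_name),
    )
    return new, enc


def design_matrix(dataset: Dataset, add_intercept: bool = True):
    """Numeric design matrix and column names (intercept first when present)."""
    cols = list(dataset.numeric)
    X = dataset.frame[cols].to_numpy(dtype=float)
    names = list(cols)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["Intercept", *names]
    return X, names


def response_function_decomposition(fit, encoding: DummyEncoding) -> dict:
    """Per-level effective intercepts implied by an intercept + indicators fit.

    With reference level omitted, the response function for the reference
    category is ``beta0 + (slopes)``; for a non-reference level ``k`` the
    intercept shifts to ``beta0 + beta_k``.  Returns
    ``{"intercepts": {level: value}, "slopes": {name: value}}`` where slopes
    are the coefficients of the remaining (non-indicator) predictors.
    """
    names = list(fit.names)
    if "Intercept" not in names:
        raise ConfigError("decomposition requires an intercept term in the fit")
    missing = [c for c in encoding.columns if c not in names]
    if missing:
        raise ConfigError(
            f"fit lacks coefficient(s) for indicator column(s): {missing}"
        )
    est = dict(zip(names, fit.params))
    beta0 = est["Intercept"]
    intercepts = {encoding.reference_level: beta0}
    for level, col in zip(encoding.non_reference_levels, encoding.columns):
        intercepts[level] = beta0 + est[col]
    slopes = {
        k: v for k, v in est.items()
        if k != "Intercept" and k not in encoding.columns
    }
    return {"intercepts": intercepts, "slopes": slopes}
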