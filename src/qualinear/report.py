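"""Model-comparison artifacts: actual-vs-predicted tables and MSE comparison.

The central comparison is per-observation absolute differences between the
actual response and each model's prediction, summarized by their arithmetic
means.  Averages are always recomputed from the columns they summarize —
never copied from a caller-supplied summary — which guards against
transposed or stale summary rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["build_comparison", "build_mse_table", "to_markdown"]

COMPARISON_COLUMNS = [
    "actual", "predicted_mlr", "absdiff_mlr",
    "predicted_flr", "absdiff_flr", "flr_lower", "flr_upper",
]


def build_comparison(actual, mlr_pred, flr_pred):
    """Actual-vs-predicted table with absolute differences and their means.

    Parameters
    ----------
    actual, mlr_pred : array-like
        Observed responses and the linear-regression predictions.
    flr_pred : sequence of FuzzyPrediction, or array-like
        Fuzzy predictions (central + support) or bare central values.

    Returns
    -------
    (pandas.DataFrame, float, float)
        Per-row comparison table, mean absolute difference for the linear
        model, and mean absolute difference for the fuzzy model.
    """
    a = np.asarray(actual, dtype=float).ravel()
    m = np.asarray(mlr_pred, dtype=float).ravel()
    if hasattr(flr_pred[0], "central"):
        fc = np.array([p.central for p in flr_pred])
        fl = np.array([p.lower for p in flr_pred])
        fu = np.array([p.upper for p in flr_pred])
    else:
        fc = np.asarray(flr_pred, dtype=float).ravel()
        fl = fu = fc
    if a.size == 0:
        raise DataError("empty comparison")
    if not (a.size == m.size == fc.size):
        raise DataError(
            f"length mismatch: actual {a.size}, mlr {m.size}, flr {fc.size}"
        )
    rows = pd.DataFrame({
        "actual": a,
        "predicted_mlr": m,
        "absdiff_mlr": np.abs(a - m),
        "predicted_flr": fc,
        "absdiff_flr": np.abs(a - fc),
        "flr_lower": fl,
        "flr_upper": fu,
    })
    return rows, float(rows["absdiff_mlr"].mean()), float(rows["absdiff_flr"].mean())


def check_summary_row(rows: pd.DataFrame, claimed_mlr: float, claimed_flr: float,
                      atol: float = 5e-3) -> bool:
    """Compare a user-supplied summary row against recomputed column means.

    Emits a warning (and returns False) when they disagree beyond ``atol`` —
    published comparison tables occasionally carry transposed averages.
    """
    got_mlr = float(rows["absdiff_mlr"].mean())
    got_flr = float(rows["absdiff_flr"].mean())
    ok = abs(got_mlr - claimed_mlr) <= atol and abs(got_flr - claimed_flr) <= atol
    if not ok:
        warnings.warn(
            "supplied averages "
            f"(MLR {claimed_mlr}, FLR {claimed_flr}) disagree with recomputed "
            f"column means (MLR {got_mlr:.4f}, FLR {got_flr:.4f})",
            stacklevel=2,
        )
    return ok


def build_mse_table(mse_lm: float, mse_net: float,
                    mse_net_unscaled: float | None = None) -> pd.DataFrame:
    """Two-model mean-squared-error comparison table.

    ``mse_lm`` is on raw response units while ``mse_net`` is on the [0,1]
    scaled response, so the two are not unit-comparable; the note column
    records this, and the back-transformed network MSE can be appended as a
    third, comparable row.
    """
    for name, v in (("mse_lm", mse_lm), ("mse_net", mse_net)):
        if v < 0:
            raise ConfigError(f"{name} must be non-negative, got {v}")
    rows = [
        {"Model": "Linear regression (MSE lm)", "Error obtained": mse_lm,
         "Note": "raw response units"},
        {"Model": "MLFFNN (MSE net)", "Error obtained": mse_net,
         "Note": "scaled response (not unit-comparable to MSE lm)"},
    ]
    if mse_net_unscaled is not None:
        if mse_net_unscaled < 0:
            raise ConfigError("mse_net_unscaled must be non-negative")
        rows.append({"Model": "MLFFNN (MSE net, back-transformed)",
                     "Error obtained": mse_net_unscaled,
                     "Note": "raw response units"})
    return pd.DataFrame(rows)


def to_markdown(frame: pd.DataFrame, float_fmt: str = "%.4f") -> str:
    """Render a table as GitHub-style markdown with stable float formatting."""
    f = frame.copy()
    for c in f.columns:
        if np.issubdtype(f[c].dtype, np.floating):
            f[c] = f[c].map(lambda v: float_fmt % v)
    header = "| " + " | ".join(str(c) for c in f.columns) + " |"
    sep = "|" + "|".join([" --- "] * len(f.columns)) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |"
            for row in f.itertuples(index=False)]
    return "\n".join([header, sep, *body])
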