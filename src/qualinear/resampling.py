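"""Case-resampling bootstrap and random train/test partitioning.

The published procedure first inflates the sample by drawing whole cases
with replacement (a case-resampling bootstrap of size 10000) and then splits
the enlarged pseudo-sample 70:30.  Because the regression split and the
network split are drawn by two independent calls in that procedure, a single
root seed here feeds *named substreams*, one per stage, so the whole run is
reproducible from one integer while the stages stay independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import ConfigError, EmptyDatasetError

__all__ = ["SplitSpec", "substream", "bootstrap_resample", "split_train_test"]

# Fixed substream registry: position defines the spawn key, so adding a new
# stage at the end never perturbs existing streams.
_STREAMS = ("bootstrap", "split-lm", "split-nn", "nn-init", "synthetic")


def substream(seed: int, name: str) -> np.random.Generator:
    """Seeded generator for a named pipeline stage.

    Distinct names give statistically independent streams derived from the
    same root seed.
    """
    if name not in _STREAMS:
        raise ConfigError(f"unknown substream {name!r}; expected one of {_STREAMS}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS.index(name),))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification.

    ``rounding_rule`` decides how the train size ``train_fraction * n`` is
    rounded: ``"half_even"`` (banker's rounding, matching R's ``round``) or
    ``"floor"``.  When ``n >= 2`` both parts are forced non-empty.
    """

    train_fraction: float = 0.70
    seed: int = 0
    rounding_rule: str = "half_even"

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie strictly in (0, 1)")
        if self.rounding_rule not in ("half_even", "floor"):
            raise ConfigError(f"unknown rounding_rule {self.rounding_rule!r}")

    def train_size(self, n: int) -> int:
        raw = self.train_fraction * n
        if self.rounding_rule == "half_even":
            k = int(round(raw))
        else:
            k = math.floor(raw)
        # keep both parts non-empty whenever possible
        return min(max(k, 1), n - 1)


def _frame_of(data):
    if isinstance(data, Dataset):
        return data.frame, data.with_frame
    if isinstance(data, pd.DataFrame):
        return data, lambda f: f
    raise ConfigError(f"expected Dataset or DataFrame, got {type(data).__name__}")


def bootstrap_resample(data, size: int, seed=None, rng: np.random.Generator | None = None):
    """Draw ``size`` whole rows uniformly with replacement.

    Every output row is an exact copy of some input row; the bootstrap never
    invents values.  Accepts a :class:`Dataset` or a bare DataFrame and
    returns the same kind.
    """
    frame, rebuild = _frame_of(data)
    if len(frame) == 0:
        raise EmptyDatasetError("cannot resample an empty dataset")
    if size < 1:
        raise ConfigError("bootstrap size must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(frame), size=size)
    out = frame.iloc[idx].reset_index(drop=True)
    return rebuild(out)


def split_train_test(data, spec: SplitSpec, rng: np.random.Generator | None = None):
    """Random disjoint train/test partition covering all rows.

    Sizes follow ``spec``; the partition is reproducible from ``spec.seed``
    unless an explicit generator is supplied (the pipeline passes stage
    substreams).
    """
    frame, rebuild = _frame_of(data)
    n = len(frame)
    if n < 2:
        raise EmptyDatasetError("need at least 2 rows to split")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = spec.train_size(n)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:k])
    test_idx = np.sort(perm[k:])
    train = frame.iloc[train_idx].reset_index(drop=True)
    test = frame.iloc[test_idx].reset_index(drop=True)
    return rebuild(train), rebuild(test)
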