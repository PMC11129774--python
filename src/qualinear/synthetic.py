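"""Synthetic datasets with the structure of the depression-treatment example.

The generator draws ages uniformly over an integer range, assigns one of
several treatment labels with given probabilities, and produces the response

    effectiveness = beta0 + beta_age * age + effect[treatment] + N(0, noise_sd)

— a linear model with one quantitative predictor and additive category
effects (the reference category's effect is 0).  Defaults mirror the
worked example's fitted world: intercept 7.948, age slope 0.919, treatment
effects A=25.075, B=8.013 relative to reference C, ages 19..67 as in the
printed sample rows, n=24 cases, and noise standard deviation 2 (a realistic
residual scale for an effectiveness score spanning roughly 25-70 points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import ConfigError

__all__ = ["SyntheticConfig", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 24
    beta0: float = 7.948
    beta_age: float = 0.919
    effect_per_level: dict = field(
        default_factory=lambda: {"A": 25.075, "B": 8.013, "C": 0.0})
    age_range: tuple = (19, 67)
    noise_sd: float = 2.0
    level_probabilities: dict | None = None  # default: uniform over levels
    integer_ages: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.effect_per_level:
            raise ConfigError("at least one category level is required")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be (low, high) with low <= high")
        probs = self.level_probabilities
        if probs is not None:
            if set(probs) != set(self.effect_per_level):
                raise ConfigError("level_probabilities keys must match effect_per_level")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-12 or any(p < 0 for p in probs.values()):
                raise ConfigError(f"probabilities must be >= 0 and sum to 1, got {total}")

    @property
    def levels(self) -> tuple:
        return tuple(sorted(self.effect_per_level))

    @property
    def probabilities(self) -> np.ndarray:
        if self.level_probabilities is None:
            k = len(self.levels)
            return np.full(k, 1.0 / k)
        return np.array([self.level_probabilities[l] for l in self.levels])

    def to_json(self, **kw) -> str:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        return json.dumps(d, **kw)


def generate(config: SyntheticConfig,
             rng: np.random.Generator | None = None) -> Dataset:
    """Draw one dataset; reproducible from ``config.seed`` unless ``rng`` is given."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.integer_ages:
        age = rng.integers(lo, hi + 1, size=config.n).astype(float)
    else:
        age = rng.uniform(lo, hi, size=config.n)
    levels = np.array(config.levels, dtype=object)
    treatment = rng.choice(levels, size=config.n, p=config.probabilities)
    effects = np.array([config.effect_per_level[t] for t in treatment])
    noise = rng.normal(0.0, config.noise_sd, size=config.n) if config.noise_sd > 0 \
        else np.zeros(config.n)
    effectiveness = config.beta0 + config.beta_age * age + effects + noise
    frame = pd.DataFrame({
        "effectiveness": effectiveness,
        "age": age,
        "treatment": treatment.astype(str),
    })
    return Dataset(frame=frame, response="effectiveness",
                   numeric=("age",), categorical=("treatment",))
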