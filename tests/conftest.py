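import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from qualinear import Dataset, SyntheticConfig, encode_dummies, generate


@pytest.fixture
def treatment_frame():
    """Tiny complete table in the shape of the worked example."""
    return pd.DataFrame({
        "effectiveness": [56.0, 41.0, 40.0, 28.0, 55.0],
        "age": [21.0, 23.0, 30.0, 19.0, 28.0],
        "treatment": ["A", "B", "C", "C", "B"],
    })


@pytest.fixture
def treatment_dataset(treatment_frame):
    return Dataset(frame=treatment_frame, response="effectiveness",
                   numeric=("age",), categorical=("treatment",))


@pytest.fixture
def encoded_dataset(treatment_dataset):
    ds, enc = encode_dummies(treatment_dataset, "treatment", "C")
    return ds, enc


@pytest.fixture
def synthetic_noisy():
    """Moderate-noise synthetic dataset, encoded and ready for fitting."""
    ds = generate(SyntheticConfig(n=60, noise_sd=2.0, seed=42))
    encoded, enc = encode_dummies(ds, "treatment")
    return encoded, enc


@pytest.fixture
def rng():
    return np.random.default_rng(20240427)
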