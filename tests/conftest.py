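import numpy as np
import pandas as pd
import pytest

from airseg.data_prep import CaseTable, split_train_valid_test
from airseg.mlp import TrainConfig


def make_linear_table(n=500, seed=0, noise=0.0, slope=2.0, intercept=3.0):
    """Toy table with y = slope*x1 + intercept (+ optional noise)."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(-1.0, 1.0, size=n)
    x2 = rng.uniform(0.0, 5.0, size=n)
    y = slope * x1 + intercept + noise * rng.normal(size=n)
    frame = pd.DataFrame({"T": x1, "WS": x2, "O3": y - y.min() + 1.0})
    return CaseTable(frame=frame, target="O3", predictors=("T", "WS"),
                     provenance={"source": "toy-linear"})


@pytest.fixture
def linear_table():
    return make_linear_table()


@pytest.fixture
def linear_split(linear_table):
    return split_train_valid_test(linear_table, seed=11)


@pytest.fixture
def fast_cfg():
    # small restart/epoch budget keeps unit tests quick
    return TrainConfig(hidden_units=6, max_epochs=120, restarts=2, seed=5)


def make_noisy_table(n=1200, seed=0, hetero=1.5):
    """Nonlinear table with target-level-dependent noise (for segmentation)."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0.0, 1.0, size=n)
    x2 = rng.uniform(0.0, 1.0, size=n)
    signal = 5.0 + 40.0 * x1**2 + 20.0 * x2
    y = signal * np.exp(hetero * 0.2 * rng.normal(size=n))
    frame = pd.DataFrame({"T": x1, "I": x2, "NO": y})
    return CaseTable(frame=frame, target="NO", predictors=("T", "I"),
                     provenance={"source": "toy-noisy"})


@pytest.fixture
def noisy_table():
    return make_noisy_table()
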