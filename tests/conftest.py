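import numpy as np
import pandas as pd
import pytest

from fittree import (
    CohortConfig,
    CostMatrix,
    LabeledDataset,
    default_bmi_standard,
    generate_cohort,
)


@pytest.fixture(scope="session")
def standard():
    return default_bmi_standard()


@pytest.fixture()
def four_point_dataset():
    """{14: a, 15: a, 19: b, 21: b} on one continuous attribute."""
    frame = pd.DataFrame({"x": [14.0, 15.0, 19.0, 21.0], "label": ["a", "a", "b", "b"]})
    return LabeledDataset(frame, {"x": "continuous"})


@pytest.fixture()
def xor_dataset():
    frame = pd.DataFrame(
        {
            "a": ["0", "0", "1", "1"],
            "b": ["0", "1", "0", "1"],
            "label": ["no", "yes", "yes", "no"],
        }
    )
    return LabeledDataset(frame, {"a": "categorical", "b": "categorical"})


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Freshman-band-labeled cohort with zero label noise."""
    config = CohortConfig(n=2000, seed=11, noise_rate=0.0)
    return generate_cohort(config), config


def random_dataset(rng: np.random.Generator, n: int = 40, n_classes: int = 3) -> LabeledDataset:
    """A small random mixed-attribute dataset for equivalence fixtures."""
    frame = pd.DataFrame(
        {
            "x": np.round(rng.normal(0.0, 1.0, n), 3),
            "y": np.round(rng.uniform(-2.0, 2.0, n), 3),
            "c": rng.choice(["u", "v", "w"], n),
            "label": rng.choice([f"k{i}" for i in range(n_classes)], n),
        }
    )
    return LabeledDataset(frame, {"x": "continuous", "y": "continuous", "c": "categorical"})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def skew_costs():
    """Distinct per-class row costs over three classes."""
    return CostMatrix.from_mapping(
        {"k0": {"k1": 5.0, "k2": 5.0}, "k1": {"k0": 2.0, "k2": 2.0}},
        labels=("k0", "k1", "k2"),
    )
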