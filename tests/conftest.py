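import numpy as np
import pytest

from cardiokit import eavsro, synthetic_data
from cardiokit.feature_weighting import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_bounds():
    return eavsro.Bounds(lower=np.zeros(3), upper=np.ones(3))


@pytest.fixture
def small_table():
    """Small synthetic cohort: 2 informative + 12 noise columns, 120 rows."""
    spec = synthetic_data.SyntheticSpec(n_rows=120, class_counts=(60, 60), seed=7)
    return synthetic_data.generate_table(spec)


@pytest.fixture
def separable_table():
    """Linearly separable fixture with a guaranteed margin of 1."""
    return synthetic_data.generate_separable_table(n_rows=200, margin=1.0, seed=3)


@pytest.fixture
def tiny_contingency_table():
    """Binary column whose class-by-bin contingency is [[8, 2], [2, 8]]."""
    values = np.array([0.0] * 8 + [1.0] * 2 + [0.0] * 2 + [1.0] * 8)
    labels = np.array([0] * 10 + [1] * 10)
    return FeatureTable(matrix=values[:, None], labels=labels, column_names=["x"])
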