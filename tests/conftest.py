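import numpy as np
import pytest

from mitn import CategoricalSeries, DatasetTable, PlantedSpec, generate_planted_dataset


def series(values):
    return CategoricalSeries.from_values(np.asarray(values))


@pytest.fixture
def rng():
    return np.random.default_rng(20220907)


@pytest.fixture
def four_feature_table(rng):
    """A fixed seeded table with 4 categorical features and a binary class."""
    n = 80
    y = rng.integers(0, 2, size=n)
    f0 = (y + rng.integers(0, 2, size=n)) % 3          # class-informative
    f1 = (f0 + rng.integers(0, 2, size=n)) % 3         # redundant with f0
    f2 = rng.integers(0, 3, size=n)                    # noise
    f3 = rng.integers(0, 2, size=n) ^ y                # informative, other shape
    feats = tuple(series(f) for f in (f0, f1, f2, f3))
    return DatasetTable(features=feats, names=("f0", "f1", "f2", "f3"),
                        class_column=series(y))


@pytest.fixture
def small_planted():
    """A compact planted dataset: 3 informative, 2 redundant, 10 noise."""
    return generate_planted_dataset(
        PlantedSpec(n_informative=3, n_redundant=2, n_noise=10, n_obs=300, seed=11))
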