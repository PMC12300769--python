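import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from sdml.data import FeatureTable

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("sdml").setLevel(logging.WARNING)


def make_table(X: np.ndarray, y: np.ndarray | None = None,
               names: list[str] | None = None, target: str = "y",
               kinds: dict | None = None) -> FeatureTable:
    """Build a FeatureTable from plain arrays."""
    names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    if y is not None:
        df[target] = y
    return FeatureTable(df, target_name=target if y is not None else None,
                        column_kinds=kinds or {})


@pytest.fixture(scope="session")
def linear_table():
    """y = 3*x1 + tiny noise; x2 is independent noise."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(200, 2))
    y = 3 * X[:, 0] + rng.normal(0, 0.01, 200)
    return make_table(X, y)


@pytest.fixture(scope="session")
def default_train():
    """The default synthetic fixture: 75% training split of a 616-row table."""
    from sdml.data import SplitSpec, split_train_test
    from sdml.synthdata import GeneratorSpec, simulate_dataset

    table, _ = simulate_dataset(GeneratorSpec(n=616, seed=11))
    train, test = split_train_test(table, SplitSpec(0.75, 11))
    return train, test


@pytest.fixture(scope="session")
def default_augmented(default_train):
    """Factor-9 augmentation of the default 462-row training fixture."""
    from sdml.augment import augment_dataset

    train, _ = default_train
    return augment_dataset(train, seed=11)
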