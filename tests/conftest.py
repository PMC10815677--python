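import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methylpanel.data_model import MethylationDataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def build_dataset(values, groups, columns=None, history=None, index=None):
    """Assemble a MethylationDataset from a plain array for tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if columns is None:
        # one amplicon per pair of columns so every CpG has a mate
        columns = [f"{(j // 2) + 1:02d}_CpG_{(j % 2) + 1}" for j in range(p)]
    if index is None:
        index = [f"s{i + 1:03d}" for i in range(n)]
    vdf = pd.DataFrame(values, index=pd.Index(index, name="sample_id"), columns=columns)
    ds = MethylationDataset.from_values(vdf, list(groups))
    if history is not None:
        ds.metadata["uca_history"] = list(history)
    return ds


@pytest.fixture
def make_ds():
    return build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def random_cohort(rng, n_cases=30, n_controls=30, p=6, effect=0.0, columns=None):
    """A quick unstructured cohort: uniform noise plus a case shift."""
    n = n_cases + n_controls
    values = rng.uniform(0.05, 0.6, size=(n, p))
    values[:n_cases] += effect
    values = np.clip(values, 0.0, 1.0)
    groups = ["case"] * n_cases + ["control"] * n_controls
    return build_dataset(values, groups, columns=columns)


@pytest.fixture
def make_cohort():
    return random_cohort
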