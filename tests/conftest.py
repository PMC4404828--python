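import numpy as np
import pandas as pd
import pytest

from mcsf import load_arena_config


@pytest.fixture(scope="session")
def arena():
    return load_arena_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(values: dict, groups, trials=("1",)) -> pd.DataFrame:
    """Parameter table from per-column value lists; row i of each trial is
    rat r{i} with group groups[i]."""
    n = len(groups)
    tuples = [(f"r{i}", groups[i], t) for t in trials for i in range(n)]
    idx = pd.MultiIndex.from_tuples(tuples, names=["rat_id", "group", "trial"])
    return pd.DataFrame({k: list(v) * len(trials) if len(v) == n else v
                         for k, v in values.items()}, index=idx)
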