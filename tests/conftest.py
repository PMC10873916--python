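import numpy as np
import pandas as pd
import pytest

from netpsych import (ItemMeta, ItemResponseTable, make_random_sparse_ggm,
                      sample_ordinal_responses)


@pytest.fixture(scope="session")
def sparse_spec():
    """Moderate 10-node ground-truth network used across modules."""
    return make_random_sparse_ggm(p=10, edge_density=0.2, seed=42,
                                  n_respondents=1000)


@pytest.fixture(scope="session")
def sparse_table(sparse_spec):
    return sample_ordinal_responses(sparse_spec)


@pytest.fixture()
def toy_items():
    """Tiny raw survey table: 2 PHQ items, 2 stressor domains, 1 support."""
    values = pd.DataFrame({
        "PHQ1": [0, 1, 2, 3, 1],
        "PHQ2": [1, 1, 3, 2, 0],
        "FIN": [0, 2, 4, 1, 3],
        "WRK": [0, 0, 4, 2, 1],
        "SSFm": [3, 5, 1, 7, 4],
    })
    meta = {
        "PHQ1": ItemMeta("PHQ", 0, 3), "PHQ2": ItemMeta("PHQ", 0, 3),
        "FIN": ItemMeta("STRESSOR", 0, 4), "WRK": ItemMeta("STRESSOR", 0, 4),
        "SSFm": ItemMeta("SUPPORT", 1, 7),
    }
    return ItemResponseTable(values=values, item_meta=meta,
                             group=pd.Series([0, 1, 0, 1, 0]))


def random_correlation(rng, p=4, n=60):
    """Well-conditioned sample correlation matrix."""
    return np.corrcoef(rng.standard_normal((p, n)))
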