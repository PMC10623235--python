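from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pairscreen.simulate import ITEM_COLUMNS


def make_table(items: np.ndarray, ids=None) -> pd.DataFrame:
    """Build a canonical response table from an (n, 9) integer/NaN array."""
    items = np.asarray(items, dtype=object)
    table = pd.DataFrame(items, columns=ITEM_COLUMNS)
    table = table.where(pd.notna(table)).astype("Int64")
    table.insert(0, "id", ids if ids is not None else np.arange(1, len(table) + 1))
    return table


def make_labeled_pair_data(a, b, labels, pair=(2, 4)) -> pd.DataFrame:
    """Minimal labelled table carrying only one item pair plus labels."""
    i, j = pair
    return pd.DataFrame(
        {
            "id": np.arange(1, len(a) + 1),
            f"item{i}": np.asarray(a, dtype=np.int64),
            f"item{j}": np.asarray(b, dtype=np.int64),
            "label": np.asarray(labels, dtype=bool),
        }
    )


@pytest.fixture(scope="session")
def labeled_4025():
    """A preprocessed synthetic sample the size of a realistic screening study."""
    import pairscreen as ps

    cfg = ps.default_config(n_respondents=4025, seed=42)
    labeled, _ = ps.preprocess(ps.generate_responses(cfg))
    return labeled


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end split + CV plan for fast pipeline tests."""
    import pairscreen as ps

    cfg = ps.default_config(n_respondents=1200, seed=7)
    labeled, _ = ps.preprocess(ps.generate_responses(cfg))
    train, test = ps.split_dataset(labeled, 0.7, seed=7)
    plan = ps.make_cv_folds(train, k=5, seed=7)
    return labeled, train, test, plan
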