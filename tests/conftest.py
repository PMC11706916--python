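import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from cropsift.io import CountTable
from cropsift.synthetic import synthetic_reference_set
from cropsift.transform import attribute_transform


@pytest.fixture
def toy_counts() -> CountTable:
    """3 weed taxa (BHH, SFL, unclassified) x 2 samples."""
    counts = pd.DataFrame(
        {"s1": [10, 5, 2], "s2": [0, 8, 1]},
        index=["taxon_a", "taxon_b", "taxon_c"],
    )
    category = pd.Series("weed", index=counts.index)
    codes = pd.Series(["BHH", "SFL", "UNCLASSIFIED"], index=counts.index)
    return CountTable(counts, category, codes)


@pytest.fixture
def mixed_counts() -> CountTable:
    """Counts with grain, rachis, weed and other rows for screening tests."""
    counts = pd.DataFrame(
        {
            "s1": [100, 10, 12, 3, 1],
            "s2": [4, 2, 30, 25, 0],
            "s3": [50, 5, 0, 0, 7],
        },
        index=["barley_grain", "barley_rachis", "weed_x", "weed_y", "nutshell"],
    )
    category = pd.Series(
        ["grain", "rachis", "weed", "weed", "other"], index=counts.index
    )
    codes = pd.Series(
        [pd.NA, pd.NA, "SFL", "BHH", pd.NA], index=counts.index
    )
    return CountTable(counts, category, codes)


@pytest.fixture(scope="session")
def reference():
    """Well-separated synthetic four-group reference (session-cached)."""
    return synthetic_reference_set(seed=11, n_per_group=10)


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "counts.csv"
    path.write_text(
        "Taxon,Codes,s1,s2\n"
        "taxon_a,BHH,10,\n"
        "taxon_b,SFL,5,8\n"
        "taxon_c,,2,1\n"
    )
    return path


def random_count_table(rng, n_taxa=8, n_samples=4) -> CountTable:
    from cropsift.io import ATTRIBUTE_CODES

    counts = pd.DataFrame(
        rng.integers(0, 30, size=(n_taxa, n_samples)),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    counts.iloc[0, :] = np.maximum(counts.iloc[0, :], 1)  # no empty samples
    codes = pd.Series(
        [ATTRIBUTE_CODES[i % 6] for i in range(n_taxa)], index=counts.index
    )
    return CountTable(counts, pd.Series("weed", index=counts.index), codes)
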