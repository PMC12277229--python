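import numpy as np
import pandas as pd
import pytest

from tubewell_risk.core_data import COLUMNS, Dataset, load_guidelines


@pytest.fixture(scope="session")
def registry():
    return load_guidelines()


def build_dataset(n=None, **cols) -> Dataset:
    """Construct a Dataset from per-column lists, padding with benign defaults."""
    lengths = [len(v) for v in cols.values() if isinstance(v, (list, tuple))]
    n = n or (max(lengths) if lengths else 1)
    defaults = {
        "school": "Test School", "union": "Bagoan",
        "longitude": 88.6, "latitude": 23.7, "depth": 300.0, "ph": 7.0,
        "ec": 900.0, "tds": 460.0, "temperature": 26.0, "salinity": 0.4,
        "fe": 0.5, "as": 0.01,
    }
    data = {}
    data["sample_id"] = cols.get("sample_id", [f"S{i + 1}" for i in range(n)])
    for c in COLUMNS[1:]:
        v = cols.get(c, defaults[c])
        data[c] = list(v) if isinstance(v, (list, tuple)) else [v] * n
    return Dataset(df=pd.DataFrame(data, columns=list(COLUMNS)), provenance="test")


def random_dataset(rng: np.random.Generator, n: int) -> Dataset:
    """Unstructured random dataset spanning the guideline thresholds."""
    unions = rng.choice(["Bagoan", "Dariapur", "Mohajanpur", "Monakhali"], size=n)
    return build_dataset(
        n=n,
        union=unions.tolist(),
        depth=rng.uniform(100, 560, n).tolist(),
        ph=rng.uniform(5.5, 9.5, n).tolist(),
        ec=rng.uniform(0, 1800, n).tolist(),
        tds=rng.uniform(0, 1500, n).tolist(),
        fe=rng.uniform(0, 5, n).tolist(),
        **{"as": rng.uniform(0, 0.5, n).tolist()},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
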