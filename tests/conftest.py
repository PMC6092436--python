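import numpy as np
import pytest

from abundrare import CountMatrix, RelAbundanceMatrix, SampleTable


@pytest.fixture
def toy_counts() -> CountMatrix:
    counts = np.array([
        [5, 0, 3],
        [1, 2, 0],
        [0, 7, 1],
        [2, 1, 4],
    ])
    return CountMatrix(["o1", "o2", "o3", "o4"], ["s1", "s2", "s3"], counts)


@pytest.fixture
def random_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(5, size=(30, 8))
    counts[0] += 1  # guarantee nonzero columns
    return CountMatrix([f"o{i}" for i in range(30)], [f"s{j}" for j in range(8)], counts)


def ra_from(counts: np.ndarray, otu_prefix="o", sample_prefix="s") -> RelAbundanceMatrix:
    counts = np.asarray(counts, dtype=float)
    ra = counts / counts.sum(axis=0)
    return RelAbundanceMatrix(
        [f"{otu_prefix}{i}" for i in range(counts.shape[0])],
        [f"{sample_prefix}{j}" for j in range(counts.shape[1])],
        ra,
    )


@pytest.fixture
def coastal_meta() -> SampleTable:
    import pandas as pd

    n = 9
    lat = np.linspace(21.0, 24.0, n)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(n)],
        "station": [f"ST{j}" for j in range(n)],
        "bay": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
        "layer": ["surface", "bottom", "surface"] * 3,
        "latitude": lat,
        "longitude": np.full(n, 112.0),
        "temperature": np.linspace(20, 28, n),
        "salinity": np.linspace(30, 33, n),
        "pH": np.linspace(7.9, 8.2, n),
    }))
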