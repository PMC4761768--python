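import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from distdecay.containers import OccurrenceMatrix, PairwiseMatrix, SiteTable
import pandas as pd

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_symmetric(n: int, rng: np.random.Generator, kind: str = "distance") -> PairwiseMatrix:
    """A random valid PairwiseMatrix with labels s1..sn."""
    m = rng.uniform(0.05, 0.95, (n, n))
    m = (m + m.T) / 2
    ids = [f"s{i + 1}" for i in range(n)]
    return PairwiseMatrix(ids, m, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def occ3():
    """Three sites with hand-checkable overlaps.

    A: {x, y, z}; B: {y, z, w}; C: {w}
    """
    inc = np.array(
        [
            [1, 1, 1, 0],
            [0, 1, 1, 1],
            [0, 0, 0, 1],
        ]
    )
    return OccurrenceMatrix(["A", "B", "C"], ["x", "y", "z", "w"], inc)


@pytest.fixture
def sites3():
    df = pd.DataFrame(
        {
            "site_id": ["A", "B", "C"],
            "lon": [100.0, 101.0, 102.0],
            "lat": [25.0, 26.0, 27.0],
            "mean_elev": [1500.0, 4200.0, 2000.0],
            "elev_range": [300.0, 900.0, 500.0],
            "area": [1000.0, 2000.0, 1500.0],
            "env1": [0.1, 0.5, 0.9],
            "env2": [1.0, 0.0, -1.0],
        }
    )
    return SiteTable(df)
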