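import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """A tiny taxa x samples count table with zeros, ties, and a dominant taxon."""
    from ednasim import ReadTable

    counts = np.array(
        [
            [5, 0, 2, 7],
            [0, 0, 0, 0],
            [10, 3, 3, 1],
            [5, 3, 0, 2],
        ]
    )
    return ReadTable(counts, taxon_ids=["a", "b", "c", "d"], sample_ids=["s1", "s2", "s3", "s4"])


@pytest.fixture
def random_table(rng):
    """A moderately sized random count table (some taxa never observed)."""
    from ednasim import ReadTable

    counts = rng.negative_binomial(2, 0.05, size=(40, 12))
    counts[rng.random(size=counts.shape) < 0.3] = 0
    counts[5] = 0  # one taxon never observed
    counts[:, 3] += 1  # guard against a zero-depth column
    return ReadTable(counts)
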