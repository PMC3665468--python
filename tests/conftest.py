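import numpy as np
import pytest

from prefrank.rankcore import RankingTable, rank_agg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(k: int, n: int, rng) -> RankingTable:
    """Uniform random rankings aggregated into a table."""
    rows = np.stack([rng.permutation(k) + 1 for _ in range(n)])
    return rank_agg(rows)


@pytest.fixture
def table_factory(rng):
    def make(k=4, n=50):
        return random_table(k, n, rng)
    return make
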