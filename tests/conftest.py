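import numpy as np
import pandas as pd
import pytest

from vhhtrack.germline import GermlineDB
from vhhtrack.simulate import SimulationConfig, simulate_germline_db


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale time course: 8 weeks, 10 lineages, 3k reads/sample."""
    return SimulationConfig(
        seed=11,
        weeks=tuple(range(8)),
        n_responding=4,
        n_static=4,
        n_preimmune=2,
        depth=3000,
    )


@pytest.fixture(scope="session")
def small_db(small_config) -> GermlineDB:
    return simulate_germline_db(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240116)


def random_table(rng, n=20, length=12, max_freq=500) -> pd.DataFrame:
    """Random unique-sequence frequency table for property tests."""
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(list("ACGT"), size=length)))
    return pd.DataFrame(
        {
            "sequence": sorted(seqs),
            "frequency": rng.integers(1, max_freq, size=n),
        }
    )
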