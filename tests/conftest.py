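import numpy as np
import pandas as pd
import pytest

from sarlogit.outcome import RESPONSE_COLUMNS
from sarlogit.synthetic import SimulationConfig, simulate_dataset


def make_response_frame(rows):
    """Build a respondent table from a list of 5-tuples (or dicts)."""
    recs = []
    for r in rows:
        if isinstance(r, dict):
            recs.append(r)
        else:
            recs.append(dict(zip(RESPONSE_COLUMNS, r)))
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic survey shared by read-only tests."""
    return simulate_dataset(SimulationConfig(n_women=2000), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
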