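import numpy as np
import pandas as pd
import pytest

import heatmite as hm


@pytest.fixture(scope="session")
def simulated_cells():
    """One full 8-cell simulated study, shared across tests."""
    return hm.simulate_cells(seed=20230405)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fates(n_escaped, n_died, n_survived, escape_days=None, death_days=None, **labels):
    """Build a per-female fate table with given counts (and optional event days)."""
    rows = []
    fid = 0
    for fate, n, days in (
        ("escaped", n_escaped, escape_days),
        ("died", n_died, death_days),
        ("survived", n_survived, None),
    ):
        for i in range(n):
            day = 10.0 if fate == "survived" else float(days[i % len(days)] if days else 5)
            rows.append(
                {"female_id": fid, "fate": fate,
                 "fate_day": None if fate == "survived" else day,
                 "duration": day, **labels}
            )
            fid += 1
    return pd.DataFrame(rows)
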