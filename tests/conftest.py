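import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seedset import default_config, exclude_damaged_plants, generate_experiment

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_table():
    """One synthetic experiment at the default configuration."""
    return generate_experiment(default_config(rng_seed=0))


@pytest.fixture(scope="session")
def retained(default_table):
    ret, _ = exclude_damaged_plants(default_table)
    return ret


def make_forty_plant_table(n_damaged_annual=1, n_damaged_triennial=2):
    """Deterministic 40-plant table (20 per site, complete triples) with the
    requested number of damaged plants per site."""
    rows = []
    rng = np.random.default_rng(12345)
    for site, prefix, n_dmg in (
        ("annual", "A", n_damaged_annual),
        ("triennial", "T", n_damaged_triennial),
    ):
        for i in range(20):
            pid = f"{prefix}{i + 1:03d}"
            for j, treatment in enumerate(("open", "outcrossed", "autonomous")):
                produced = int(rng.integers(10, 60))
                rows.append(
                    {
                        "plant_id": pid,
                        "site": site,
                        "treatment": treatment,
                        "seeds_produced": produced,
                        "seeds_germinated": int(rng.integers(0, produced + 1) // 10),
                        "damaged": int(i < n_dmg and j == 0),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def forty_plant_table():
    return make_forty_plant_table()
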