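import logging

import numpy as np
import pandas as pd
import pytest

from skinmatch.simulate import SimConfig, default_sites, simulate_community
from skinmatch.tables import OtuTable, SampleFrame, rarefy

logging.disable(logging.INFO)


def small_config(**overrides) -> SimConfig:
    """A fast 4-couple, 4-site, shallow-depth simulation config."""
    defaults = dict(
        n_couples=4,
        body_locations=default_sites()[:4],
        n_otus=80,
        depth_floor=400,
        depth_meanlog=5.0,
        depth_sdlog=0.3,
        sigma_sex=0.0,
        sex_effect_sites=(),
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """(table, meta, truth) for a small default simulation."""
    return simulate_community(small_config())


@pytest.fixture(scope="session")
def small_rarefied(small_sim):
    table, meta, truth = small_sim
    return rarefy(table, 400, seed=1), meta


@pytest.fixture
def toy_table():
    return OtuTable(
        np.array([[3, 0], [1, 2]]),
        ("S1", "S2"),
        ("OTU1", "OTU2"),
    )


def make_meta(rows):
    """Build a SampleFrame from (sample, participant, couple, sex, location, side) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "participant", "couple", "sex", "body_location", "side"],
    ).set_index("sample_id")
    df["moisture"] = [
        {"foot": "moist", "palm": "dry", "torso": "oily"}.get(loc, "moist")
        for loc in df["body_location"]
    ]
    return SampleFrame(df)
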