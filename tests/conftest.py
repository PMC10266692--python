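import numpy as np
import pandas as pd
import pytest

from nesttrack import synthetic as syn


@pytest.fixture(scope="session")
def island():
    return syn.make_island()


@pytest.fixture(scope="session")
def small_cohort(island):
    """Two short-track animals (compact migration) for pipeline-level tests."""
    cfg = syn.SimConfig(
        seed=11, n_animals=2,
        directed_days_range={"central_atlantic": (18.0, 22.0),
                             "south_america": (80.0, 95.0)},
        migration_group_probs={"central_atlantic": 1.0, "south_america": 0.0},
        ars_days=8.0,
    )
    regions, truths, argos, dry = syn.simulate_cohort(cfg, island)
    return cfg, truths, argos, dry


def make_track(lon, lat, start="2019-01-01", freq="1D", animal_id="t",
               sd_km=0.5):
    """Build a RegularTrack from raw coordinate arrays."""
    from nesttrack.preprocessing import RegularTrack
    lon = np.asarray(lon, dtype=float)
    times = pd.date_range(start, periods=len(lon), freq=freq, tz="UTC")
    return RegularTrack(animal_id, times, lon, np.asarray(lat, dtype=float),
                        np.full(len(lon), sd_km), pd.Timedelta(freq))
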