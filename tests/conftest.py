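import numpy as np
import pandas as pd
import pytest

from storknet import synthdata


def make_fixes(bird_id, times, lons, lats):
    """Canonical fix frame from parallel lists (times as ISO strings)."""
    return pd.DataFrame(
        {
            "bird_id": str(bird_id),
            "timestamp": pd.to_datetime(list(times), utc=True),
            "lon": np.asarray(lons, dtype=float),
            "lat": np.asarray(lats, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def small_landscape():
    spec = synthdata.LandscapeSpec(
        n_sites={"Landfills": 2, "Marshes": 2, "Rice fields": 2},
        bbox=(-6.8, 36.4, -4.6, 38.0),
        seed=42,
    )
    return synthdata.gen_landscape(spec)


@pytest.fixture(scope="session")
def noiseless_tracks(small_landscape):
    spec = synthdata.MovementSpec(
        n_birds=2,
        season_start="2020-09-01",
        season_end="2020-09-15",
        gps_noise_m=0.0,
        gap_per_day=0.0,
        seed=7,
    )
    return synthdata.gen_tracks(small_landscape, spec)
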