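import numpy as np
import pandas as pd
import pytest

from airgapfill.series import CHANNELS, StationSeries, hourly_index
from airgapfill.synthetic import SyntheticConfig, generate_station


@pytest.fixture(scope="session")
def small_station() -> StationSeries:
    """Complete 2000-hour synthetic station with default noise."""
    return generate_station(SyntheticConfig(n_hours=2000, seed=11,
                                            gap_rate=0.0))


@pytest.fixture(scope="session")
def noiseless_station() -> StationSeries:
    """Deterministic station: CO equals its seasonal template."""
    cfg = SyntheticConfig(
        n_hours=3000, seed=5, noise_sd=0.0, ar_coef=0.0,
        couplings={k: (g, 0.0, b) for k, (g, _s, b) in
                   SyntheticConfig().couplings.items()},
        gap_rate=0.0)
    return generate_station(cfg)


def station_from_values(values: dict[str, np.ndarray]) -> StationSeries:
    """Build a StationSeries from raw channel arrays (others filled at 1.0)."""
    n = len(next(iter(values.values())))
    idx = hourly_index(n)
    data = {}
    for c in CHANNELS:
        if c in values:
            data[c] = np.asarray(values[c], dtype=float)
        else:
            data[c] = np.ones(n)
    return StationSeries(pd.DataFrame(data, index=idx))
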