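from datetime import datetime, timezone

import numpy as np
import pytest

from roostradar import (
    PolarSweep,
    QuantConfig,
    RadarConfig,
    RoostSpec,
    simulate_series,
)


@pytest.fixture(scope="session")
def config_360() -> RadarConfig:
    """Single-sweep 360-azimuth radar (keeps synthetic volumes small)."""
    return RadarConfig(elevation_angles=(0.9,), n_azimuths=360)


@pytest.fixture(scope="session")
def config_294() -> RadarConfig:
    return RadarConfig(elevation_angles=(0.9,), n_azimuths=294)


@pytest.fixture(scope="session")
def qc_open() -> QuantConfig:
    """Quantification config with the dBZ filters disabled."""
    return QuantConfig(dbz_min=None, dbz_max=None, mc_samples=100_000, mc_seed=11)


@pytest.fixture()
def empty_sweep(config_360) -> PolarSweep:
    n_rng = 120
    return PolarSweep(
        elevation=0.9,
        azimuth_centers=config_360.azimuth_centers(),
        range_centers=config_360.range_centers(n_rng),
        dbz=np.full((360, n_rng), np.nan),
    )


@pytest.fixture(scope="session")
def single_roost_scene(config_360, qc_open):
    """One clean roost of 10,000 birds, no clutter, no precipitation."""
    t0 = datetime(2014, 3, 1, 9, 24, tzinfo=timezone.utc)  # 05:24 local
    roost = RoostSpec(
        center=(40.0, 10.0),
        first_scan_time=t0,
        n_scans=4,
        total_birds=10_000.0,
    )
    series, manifest, annotations = simulate_series(
        config_360, [roost], seed=42, qc=qc_open
    )
    return series, manifest, annotations
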