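import numpy as np
import pandas as pd
import pytest

from ciconia import io, pipeline, simulate


def make_burst(individual="b1", t0="2020-09-01 08:00:00", speeds=None,
               climbs=None, lat0=47.0, lon0=8.0, hae0=500.0, dt=1.0,
               wind_u=None, wind_v=None):
    """Construct a GPSBurst whose raw per-step speed/climb series are exactly
    the given arrays (movement due north)."""
    speeds = np.asarray(speeds if speeds is not None else [], dtype=float)
    n = speeds.size + 1
    climbs = np.asarray(climbs if climbs is not None else np.zeros(n - 1), dtype=float)
    assert climbs.size == n - 1
    m_lat, _ = simulate.geodesic.meters_per_degree(lat0)
    lat = lat0 + np.concatenate([[0.0], np.cumsum(speeds * dt)]) / m_lat
    t = pd.Timestamp(t0).to_datetime64() + (np.arange(n) * dt * 1e9).astype("timedelta64[ns]")
    burst = io.GPSBurst(
        individual_id=individual,
        t=t.astype("datetime64[ns]"),
        lon=np.full(n, lon0),
        lat=lat,
        hae=hae0 + np.concatenate([[0.0], np.cumsum(climbs * dt)]),
        ground_elev=np.zeros(n),
        wind_u=np.full(n, wind_u, dtype=float) if wind_u is not None else None,
        wind_v=np.full(n, wind_v, dtype=float) if wind_v is not None else None,
    )
    return io.derive_kinematics(burst)


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """Three-group synthetic cohort, 2 birds per group, through the full
    pipeline. Day counts are scaled so every group still transits the
    reference segment; group flight parameters are the defaults."""
    cfg = simulate.default_config(seed=11, n_individuals_per_group=2)
    cfg.group_params["naturally_timed"].migration_days = 10
    cfg.group_params["control"].migration_days = 8
    out = tmp_path_factory.mktemp("cohort") / "run"
    rc = pipeline.RunConfig(seed=11, out_dir=str(out), sim=cfg)
    return rc, pipeline.run(rc)
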