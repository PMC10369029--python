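"""ODBA from accelerometer bursts; wind support / crosswind / airspeed.

ODBA (overall dynamic body acceleration) is computed per burst as the sum
over the three axes of the mean absolute deviation of the calibrated
acceleration from the axis mean -- a standard proxy for flapping effort.

Wind decomposition projects the annotated wind vector (U east, V north)
onto the ground-track direction: the along-track component is the wind
support (positive = tailwind), the orthogonal magnitude the crosswind,
and the airspeed is the modulus of ground vector minus wind vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geodesic
from .io import ACCBurst, GPSBurst, ValidationError
from .segmentation import CLIMBING, GLIDING

OTHER = "other"


@dataclass
class WindTriple:
    wind_support: float   # m s-1, signed; + = tailwind
    crosswind: float      # m s-1, >= 0
    airspeed: float       # m s-1, >= 0


def odba(burst: ACCBurst) -> float:
    """ODBA of one burst in m s-2 (calibration applied first)."""
    acc = burst.calibrated()
    if acc.shape[1] < 2:
        raise ValidationError("ODBA needs at least 2 samples per axis")
    dev = np.abs(acc - acc.mean(axis=1, keepdims=True))
    return float(dev.mean(axis=1).sum())


def wind_decompose(ground_u, ground_v, wind_u, wind_v):
    """Decompose wind relative to the ground-track vector.

    Accepts scalars or arrays. Returns a :class:`WindTriple` for scalar
    input, else a tuple of arrays ``(wind_support, crosswind, airspeed)``.
    A zero ground vector leaves the decomposition undefined (NaN).
    """
    gu = np.asarray(ground_u, dtype=float)
    gv = np.asarray(ground_v, dtype=float)
    wu = np.asarray(wind_u, dtype=float)
    wv = np.asarray(wind_v, dtype=float)
    scalar = gu.ndim == 0 and gv.ndim == 0 and wu.ndim == 0 and wv.ndim == 0
    gu, gv, wu, wv = np.broadcast_arrays(*np.atleast_1d(gu, gv, wu, wv))

    gmag = np.hypot(gu, gv)
    ok = gmag > 0.0
    safe = np.where(ok, gmag, 1.0)
    support = np.where(ok, (wu * gu + wv * gv) / safe, np.nan)
    wmag2 = wu**2 + wv**2
    cross = np.sqrt(np.maximum(wmag2 - support**2, 0.0))
    air = np.sqrt((gmag - support) ** 2 + cross**2)
    air = np.where(ok, air, np.nan)
    cross = np.where(ok, cross, np.nan)
    if scalar:
        return WindTriple(float(support[0]), float(cross[0]), float(air[0]))
    return support, cross, air


def daily_wind_support(lat1, lon1, lat2, lon2, mean_wind_u, mean_wind_v) -> float:
    """Wind support along a day's migration flight, m s-1.

    Projects the flight-time-averaged wind vector onto the initial
    geodesic bearing from the first to the last location of the flight.
    """
    _, bearing = geodesic.inverse(lat1, lon1, lat2, lon2)
    b = np.radians(bearing)
    return float(mean_wind_u * np.sin(b) + mean_wind_v * np.cos(b))


def ground_vectors(burst: GPSBurst) -> tuple[np.ndarray, np.ndarray]:
    """Per-step east/north ground velocity components (length n-1).

    Steps are ~1 s, so the local metres-per-degree scale at the earlier
    fix is accurate to well below measurement noise.
    """
    m_lat, m_lon = geodesic.meters_per_degree(burst.lat[:-1])
    du = np.diff(burst.lon) * m_lon / burst.dt_s
    dv = np.diff(burst.lat) * m_lat / burst.dt_s
    return du, dv


def attach_behaviour(
    acc_bursts,
    gps_bursts,
    climb_bouts,
    glide_bouts,
    max_lag_s: float = 1200.0,
) -> pd.DataFrame:
    """Label ACC bursts with the behaviour at the end of the preceding GPS burst.

    For each ACC burst the immediately preceding GPS burst of the same
    individual is located (no further back than ``max_lag_s``); the burst's
    final fix determines the behaviour: *climbing* or *gliding* if a bout
    of that kind contains it, else *other*. Returns an ODBA record table
    (individual, timestamp, odba, behaviour, altitude AGL at assignment).
    """
    by_ind_bursts: dict[str, list[GPSBurst]] = {}
    for b in gps_bursts:
        by_ind_bursts.setdefault(b.individual_id, []).append(b)
    for lst in by_ind_bursts.values():
        lst.sort(key=lambda b: b.end_time)

    # index bouts by (individual, burst start time) for containment lookups
    bout_index: dict[tuple, list] = {}
    for bout in list(climb_bouts) + list(glide_bouts):
        key = (bout.individual_id, np.datetime64(bout.burst_start_time, "ns"))
        bout_index.setdefault(key, []).append(bout)

    rows = []
    for acc in acc_bursts:
        cand = by_ind_bursts.get(acc.individual_id, [])
        ends = np.array([b.end_time for b in cand], dtype="datetime64[ns]")
        t = np.datetime64(acc.t, "ns")
        i = int(np.searchsorted(ends, t, side="right")) - 1
        behaviour = OTHER
        alt = np.nan
        if i >= 0:
            gb = cand[i]
            lag = (t - ends[i]) / np.timedelta64(1, "s")
            if lag <= max_lag_s:
                alt = float((gb.hae - gb.ground_elev)[-1])
                last_didx = gb.n - 2  # derived index of the final fix
                if last_didx >= 0:
                    for bout in bout_index.get(
                        (gb.individual_id, np.datetime64(gb.start_time, "ns")), ()
                    ):
                        if bout.start_idx <= last_didx <= bout.end_idx:
                            behaviour = (
                                CLIMBING if bout.kind == CLIMBING else GLIDING
                            )
                            break
        rows.append({
            "individual_id": acc.individual_id,
            "t": pd.Timestamp(acc.t),
            "odba": odba(acc),
            "behaviour": behaviour,
            "altitude_agl": alt,
        })
    return pd.DataFrame(rows)


def glide_airspeeds(burst: GPSBurst, glide_bouts) -> np.ndarray:
    """Per-fix airspeeds within this burst's gliding bouts.

    Requires annotated wind on the burst; steps without wind give NaN.
    """
    if burst.wind_u is None or burst.wind_v is None:
        return np.empty(0)
    gu, gv = ground_vectors(burst)
    wu = burst.wind_u[1:]
    wv = burst.wind_v[1:]
    out = []
    for bout in glide_bouts:
        sl = slice(bout.start_idx, bout.end_idx + 1)
        out.append(np.hypot(gu[sl] - wu[sl], gv[sl] - wv[sl]))
    if not out:
        return np.empty(0)
    return np.concatenate(out)
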