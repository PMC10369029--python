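"""Reading, validating and assembling GPS and accelerometer burst data.

The on-disk dialect follows Movebank conventions: one row per GPS fix with
``individual-local-identifier``, ``timestamp`` (UTC), ``location-long``,
``location-lat``, ``height-above-ellipsoid``, ``ground-elevation`` and
optional annotated ``wind-u`` / ``wind-v`` columns (m s-1, ECMWF-style U/V
at the bird's pressure level). ACC bursts live in a companion CSV with one
row per four-second burst and axis-interleaved raw samples.

A *burst* is a contiguous 1 Hz recording block; bursts are reconstructed
from the fix stream purely from time gaps (the tags record a 10-min 1 Hz
burst when the bird moves and a single fix when it is stationary, every
15 min inside the 02:00-20:00 GMT duty window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geodesic

TIMESTAMP_FMT = "%Y-%m-%d %H:%M:%S.%f"

GPS_FILE_COLUMNS = {
    "individual-local-identifier": "individual_id",
    "timestamp": "t",
    "location-long": "lon",
    "location-lat": "lat",
    "height-above-ellipsoid": "hae",
    "ground-elevation": "ground_elev",
    "wind-u": "wind_u",
    "wind-v": "wind_v",
}
GPS_REQUIRED = [c for c in GPS_FILE_COLUMNS if c not in ("wind-u", "wind-v")]

ACC_FILE_COLUMNS = [
    "individual-local-identifier", "timestamp", "samples",
    "offset-x", "gain-x", "offset-y", "gain-y", "offset-z", "gain-z",
]


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """Record contents violate an invariant (ordering, duplicates...)."""


@dataclass
class GPSBurst:
    """Ordered 1 Hz fixes plus per-fix kinematics.

    Derived arrays (``dt_s``, ``step_m``, ``ground_speed``, ``climb_rate``)
    have length n-1 and are aligned to the *later* fix of each consecutive
    pair; ``altitude_agl`` (= hae - ground elevation) is per-fix, length n.
    """

    individual_id: str
    t: np.ndarray                 # datetime64[ns]
    lon: np.ndarray
    lat: np.ndarray
    hae: np.ndarray
    ground_elev: np.ndarray
    wind_u: np.ndarray | None = None
    wind_v: np.ndarray | None = None
    # derived (filled by derive_kinematics)
    dt_s: np.ndarray | None = field(default=None, repr=False)
    step_m: np.ndarray | None = field(default=None, repr=False)
    ground_speed: np.ndarray | None = field(default=None, repr=False)
    climb_rate: np.ndarray | None = field(default=None, repr=False)
    altitude_agl: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def start_time(self):
        return self.t[0]

    @property
    def end_time(self):
        return self.t[-1]

    def t_epoch_s(self) -> np.ndarray:
        return self.t.astype("datetime64[ns]").astype("int64") / 1e9


@dataclass
class ACCBurst:
    """One tri-axial accelerometer burst (nominally 4 s at 10 Hz).

    ``samples`` is a (3, n) array of raw values in axis order
    (surge, sway, heave); ``calibration`` is (3, 2) rows of
    (offset, gain) mapping raw -> m s-2 as (raw - offset) * gain.
    """

    individual_id: str
    t: np.datetime64
    samples: np.ndarray
    calibration: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.calibration = np.asarray(self.calibration, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValidationError("ACC samples must be a (3, n) array")
        if self.calibration.shape != (3, 2):
            raise ValidationError("ACC calibration must be (3, 2) (offset, gain) rows")

    def calibrated(self) -> np.ndarray:
        off = self.calibration[:, 0][:, None]
        gain = self.calibration[:, 1][:, None]
        return (self.samples - off) * gain


def read_movebank(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Movebank-dialect GPS CSV.

    Returns ``(fixes, report)``: fixes as a typed DataFrame sorted by
    individual then time, and a row-numbered report of rejected rows
    (columns ``row`` 1-based data row number, ``reason``). Missing
    required columns raise :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in GPS_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = pd.DataFrame({"individual_id": raw["individual-local-identifier"].astype(str)})
    df["t"] = pd.to_datetime(raw["timestamp"], format="mixed", errors="coerce")
    for fcol, col in [("location-long", "lon"), ("location-lat", "lat"),
                      ("height-above-ellipsoid", "hae"), ("ground-elevation", "ground_elev")]:
        df[col] = pd.to_numeric(raw[fcol], errors="coerce")
    for fcol, col in [("wind-u", "wind_u"), ("wind-v", "wind_v")]:
        df[col] = pd.to_numeric(raw[fcol], errors="coerce") if fcol in raw.columns else np.nan

    reasons = pd.Series("", index=df.index, dtype=object)
    bad_t = df["t"].isna()
    reasons[bad_t] = "unparseable timestamp"
    for col in ("lon", "lat", "hae", "ground_elev"):
        bad = df[col].isna() & (reasons == "")
        reasons[bad] = f"non-numeric {col}"
    out_of_range = ((df["lat"].abs() > 90) | (df["lon"].abs() > 180)) & (reasons == "")
    reasons[out_of_range] = "lat/lon out of range"

    bad_mask = reasons != ""
    report = pd.DataFrame({
        "row": np.flatnonzero(bad_mask.to_numpy()) + 1,
        "reason": reasons[bad_mask].to_numpy(),
    })
    fixes = df.loc[~bad_mask].sort_values(["individual_id", "t"], kind="mergesort")
    return fixes.reset_index(drop=True), report


def assemble_bursts(fixes: pd.DataFrame, gap_threshold_s: float = 30.0) -> list[GPSBurst]:
    """Split time-sorted fixes into bursts at gaps > ``gap_threshold_s``.

    Consecutive fixes of one individual separated by at most the threshold
    share a burst; isolated fixes become single-fix (stationary) bursts.
    """
    bursts: list[GPSBurst] = []
    has_wind = "wind_u" in fixes.columns and fixes["wind_u"].notna().any()
    for ind, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("t", kind="mergesort")
        t = grp["t"].to_numpy(dtype="datetime64[ns]")
        if len(t) == 0:
            continue
        dt = np.diff(t).astype("timedelta64[ns]").astype("int64") / 1e9
        cuts = np.flatnonzero(dt > gap_threshold_s) + 1
        for idx in np.split(np.arange(len(t)), cuts):
            sub = grp.iloc[idx]
            bursts.append(GPSBurst(
                individual_id=str(ind),
                t=sub["t"].to_numpy(dtype="datetime64[ns]"),
                lon=sub["lon"].to_numpy(dtype=float),
                lat=sub["lat"].to_numpy(dtype=float),
                hae=sub["hae"].to_numpy(dtype=float),
                ground_elev=sub["ground_elev"].to_numpy(dtype=float),
                wind_u=sub["wind_u"].to_numpy(dtype=float) if has_wind else None,
                wind_v=sub["wind_v"].to_numpy(dtype=float) if has_wind else None,
            ))
    return bursts


def derive_kinematics(burst: GPSBurst) -> GPSBurst:
    """Fill per-fix kinematics in place (and return the burst).

    ground_speed_i = geodesic(fix_{i-1}, fix_i) / dt_i and
    climb_rate_i = (hae_i - hae_{i-1}) / dt_i, aligned to the later fix.
    Fixes repeating a timestamp (dt = 0) are dropped with a warning.
    """
    if burst.n >= 2:
        t = burst.t_epoch_s()
        dup = np.flatnonzero(np.diff(t) <= 0.0)
        if dup.size:
            warnings.warn(
                f"{burst.individual_id}: dropping {dup.size} fix(es) with zero/negative dt"
            )
            keep = np.setdiff1d(np.arange(burst.n), dup + 1)
            for name in ("t", "lon", "lat", "hae", "ground_elev", "wind_u", "wind_v"):
                arr = getattr(burst, name)
                if arr is not None:
                    setattr(burst, name, arr[keep])

    burst.altitude_agl = burst.hae - burst.ground_elev
    if burst.n < 2:
        empty = np.empty(0, dtype=float)
        burst.dt_s, burst.step_m = empty, empty.copy()
        burst.ground_speed, burst.climb_rate = empty.copy(), empty.copy()
        return burst

    t = burst.t_epoch_s()
    burst.dt_s = np.diff(t)
    burst.step_m, _ = geodesic.inverse(
        burst.lat[:-1], burst.lon[:-1], burst.lat[1:], burst.lon[1:]
    )
    burst.ground_speed = burst.step_m / burst.dt_s
    burst.climb_rate = np.diff(burst.hae) / burst.dt_s
    return burst


# ---------------------------------------------------------------- writers

def _format_gps(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["individual-local-identifier"] = df["individual_id"].astype(str)
    t = pd.to_datetime(df["t"])
    out["timestamp"] = t.dt.strftime(TIMESTAMP_FMT).str.slice(0, 23)
    out["location-long"] = df["lon"].map(lambda v: f"{v:.7f}")
    out["location-lat"] = df["lat"].map(lambda v: f"{v:.7f}")
    out["height-above-ellipsoid"] = df["hae"].map(lambda v: f"{v:.3f}")
    out["ground-elevation"] = df["ground_elev"].map(lambda v: f"{v:.3f}")
    for col, fcol in (("wind_u", "wind-u"), ("wind_v", "wind-v")):
        if col in df.columns and df[col].notna().any():
            out[fcol] = df[col].map(lambda v: f"{v:.3f}")
    return out


def write_movebank_csv(fixes: pd.DataFrame, path) -> None:
    """Write fixes to a Movebank-dialect CSV (lossless round trip).

    Requires strictly increasing timestamps per individual; duplicated or
    unsorted timestamps raise :class:`ValidationError`.
    """
    if len(fixes) == 0:
        raise ValidationError("no records to write")
    for ind, grp in fixes.groupby("individual_id", sort=False):
        t = pd.to_datetime(grp["t"]).to_numpy()
        if len(t) > 1 and not (np.diff(t).astype("int64") > 0).all():
            raise ValidationError(
                f"timestamps for {ind} are not strictly increasing (duplicate or unsorted)"
            )
    _format_gps(fixes).to_csv(path, index=False, lineterminator="\n")


def write_acc_csv(bursts, path) -> None:
    """Write ACC bursts (iterable of :class:`ACCBurst`) to CSV."""
    rows = []
    for b in bursts:
        interleaved = b.samples.T.reshape(-1)
        rows.append({
            "individual-local-identifier": b.individual_id,
            "timestamp": pd.Timestamp(b.t).strftime(TIMESTAMP_FMT)[:23],
            "samples": " ".join(f"{v:.4f}" for v in interleaved),
            "offset-x": f"{b.calibration[0, 0]:.6f}", "gain-x": f"{b.calibration[0, 1]:.6f}",
            "offset-y": f"{b.calibration[1, 0]:.6f}", "gain-y": f"{b.calibration[1, 1]:.6f}",
            "offset-z": f"{b.calibration[2, 0]:.6f}", "gain-z": f"{b.calibration[2, 1]:.6f}",
        })
    pd.DataFrame(rows, columns=ACC_FILE_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_acc(path) -> list[ACCBurst]:
    """Read an ACC burst CSV written by :func:`write_acc_csv`."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ACC_FILE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    raw = raw.rename(columns=lambda c: c.replace("-", "_"))
    bursts = []
    for row in raw.itertuples(index=False):
        flat = np.array(row.samples.split(), dtype=float)
        if flat.size % 3:
            raise ValidationError("interleaved sample count is not a multiple of 3")
        samples = flat.reshape(-1, 3).T
        calib = np.array([
            [float(row.offset_x), float(row.gain_x)],
            [float(row.offset_y), float(row.gain_y)],
            [float(row.offset_z), float(row.gain_z)],
        ])
        bursts.append(ACCBurst(
            individual_id=str(row.individual_local_identifier),
            t=np.datetime64(pd.Timestamp(row.timestamp)),
            samples=samples,
            calibration=calib,
        ))
    return bursts
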