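"""Flight / climbing / gliding bout segmentation inside GPS bursts.

The classification follows the soaring-gliding scheme used for stork
biologging data:

* fixes belong to a *flight* bout while the 15 s running-mean ground
  speed is >= 2.5 m s-1;
* inside flight bouts, the 15 s running-mean climb rate splits fixes into
  *climbing* (> 0.2 m s-1) and *gliding* (< 0 m s-1); rates in the
  [0, 0.2] dead zone belong to neither class;
* bouts must last at least 15 s, allowing internal interruptions of at
  most 5 s of different behaviour (same-kind runs separated by <= 5 s are
  merged before the minimum-length rule is applied); for climbing and
  gliding, a lapse into the *opposite* vertical class ends the bout --
  only dead-zone interruptions merge -- which keeps the two classes
  disjoint;
* bout summaries (climbing rate, sinking speed) average the *raw*, not
  smoothed, climb rates;
* a thermal-exit altitude is the above-ground altitude at the end of a
  climbing bout that does not end in the last 5 s of its GPS burst.

Threshold boundary senses are encoded exactly as stated above
(>= 2.5, > 0.2, < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GPSBurst

FLIGHT = "flight"
CLIMBING = "climbing"
GLIDING = "gliding"


@dataclass
class SegmentationParams:
    flight_speed_min: float = 2.5     # m s-1, smoothed ground speed
    climb_min: float = 0.2            # m s-1, smoothed climb rate
    glide_max: float = 0.0            # m s-1, smoothed climb rate
    bout_min_s: float = 15.0
    interrupt_max_s: float = 5.0
    smooth_window_s: float = 15.0
    burst_tail_exclusion_s: float = 5.0

    def validate(self) -> None:
        if not self.bout_min_s > self.interrupt_max_s:
            raise ValueError("bout_min_s must exceed interrupt_max_s")
        if not self.climb_min > self.glide_max:
            raise ValueError("climb_min must exceed glide_max")


@dataclass
class FlightBout:
    """A labelled interval of one burst.

    ``start_idx``/``end_idx`` index the burst's derived (length n-1)
    arrays, inclusive; the corresponding fixes are those indices + 1.
    """

    individual_id: str
    kind: str
    start_idx: int
    end_idx: int
    start_time: np.datetime64
    end_time: np.datetime64
    duration_s: float
    mean_raw_climb_rate: float
    mean_ground_speed: float
    end_altitude_agl: float
    burst_start_time: np.datetime64
    burst_end_time: np.datetime64

    @property
    def n_fixes(self) -> int:
        return self.end_idx - self.start_idx + 1


def smooth(series, window_s: float, dt: float) -> np.ndarray:
    """Centred running mean over an odd number of samples.

    The window spans ``round(window_s / dt)`` samples, forced odd; at the
    series edges it truncates to the available samples (no padding), so
    output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    w = int(round(window_s / dt))
    if w % 2 == 0:
        w += 1
    w = max(w, 1)
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def _nominal_dt(t_s: np.ndarray) -> float:
    if t_s.size < 2:
        return 1.0
    return float(np.median(np.diff(t_s)))


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] (inclusive) runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(int(seg[0]), int(seg[-1])) for seg in np.split(idx, cuts)]


def _merge_and_filter(runs, t_s, dt, min_s, gap_s, forbid=None) -> list[tuple[int, int]]:
    """Merge runs separated by <= gap_s of interruption, then drop merged
    runs shorter than min_s. Durations count whole samples
    (t_end - t_start + dt).

    ``forbid`` optionally marks samples that terminate a bout outright: a
    gap containing any forbidden sample is never merged across. This is
    how an excursion into the opposite vertical class ends a climbing or
    gliding bout while dead-zone wobbles only interrupt it -- and it is
    what keeps climbing and gliding bouts disjoint.
    """
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = t_s[s] - t_s[merged[-1][1]] - dt
        blocked = forbid is not None and bool(np.any(forbid[merged[-1][1] + 1:s]))
        if gap <= gap_s + 1e-9 and not blocked:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        (s, e) for s, e in merged if t_s[e] - t_s[s] + dt >= min_s - 1e-9
    ]


def _make_bout(burst: GPSBurst, kind: str, s: int, e: int, dt: float) -> FlightBout:
    t_s = burst.t_epoch_s()[1:]  # aligned to later fix
    return FlightBout(
        individual_id=burst.individual_id,
        kind=kind,
        start_idx=s,
        end_idx=e,
        start_time=burst.t[s + 1],
        end_time=burst.t[e + 1],
        duration_s=float(t_s[e] - t_s[s] + dt),
        mean_raw_climb_rate=float(np.mean(burst.climb_rate[s:e + 1])),
        mean_ground_speed=float(np.mean(burst.ground_speed[s:e + 1])),
        end_altitude_agl=float(burst.altitude_agl[e + 1]),
        burst_start_time=burst.t[0],
        burst_end_time=burst.t[-1],
    )


def detect_flight(burst: GPSBurst, params: SegmentationParams | None = None) -> list[FlightBout]:
    """Flight bouts: runs of smoothed ground speed >= the flight threshold."""
    params = params or SegmentationParams()
    if burst.ground_speed is None:
        raise ValueError("burst lacks derived kinematics; call derive_kinematics first")
    if burst.n < 2:
        return []
    t_s = burst.t_epoch_s()[1:]
    dt = _nominal_dt(t_s)
    speed_s = smooth(burst.ground_speed, params.smooth_window_s, dt)
    mask = speed_s >= params.flight_speed_min
    runs = _merge_and_filter(_runs_from_mask(mask), t_s, dt,
                             params.bout_min_s, params.interrupt_max_s)
    return [_make_bout(burst, FLIGHT, s, e, dt) for s, e in runs]


def classify_climb_glide(
    burst: GPSBurst,
    flight_bout: FlightBout,
    params: SegmentationParams | None = None,
) -> tuple[list[FlightBout], list[FlightBout]]:
    """Climbing and gliding bouts nested inside one flight bout.

    The smoothed climb rate is computed over the whole burst (edge windows
    truncate at the burst, not the bout) and then restricted to the flight
    bout before the run / gap / minimum-length rules are applied.
    """
    params = params or SegmentationParams()
    t_s = burst.t_epoch_s()[1:]
    dt = _nominal_dt(t_s)
    climb_s = smooth(burst.climb_rate, params.smooth_window_s, dt)

    lo, hi = flight_bout.start_idx, flight_bout.end_idx
    inside = np.zeros(climb_s.size, dtype=bool)
    inside[lo:hi + 1] = True

    climb_mask = (climb_s > params.climb_min) & inside
    glide_mask = (climb_s < params.glide_max) & inside
    out: list[list[FlightBout]] = []
    for kind, mask, forbid in (
        (CLIMBING, climb_mask, glide_mask),
        (GLIDING, glide_mask, climb_mask),
    ):
        runs = _merge_and_filter(_runs_from_mask(mask), t_s, dt,
                                 params.bout_min_s, params.interrupt_max_s,
                                 forbid=forbid)
        out.append([_make_bout(burst, kind, s, e, dt) for s, e in runs])
    return out[0], out[1]


def segment_burst(
    burst: GPSBurst, params: SegmentationParams | None = None
) -> tuple[list[FlightBout], list[FlightBout], list[FlightBout]]:
    """Full segmentation of one burst -> (flight, climbing, gliding) bouts."""
    params = params or SegmentationParams()
    flight = detect_flight(burst, params)
    climbs: list[FlightBout] = []
    glides: list[FlightBout] = []
    for fb in flight:
        c, g = classify_climb_glide(burst, fb, params)
        climbs.extend(c)
        glides.extend(g)
    return flight, climbs, glides


def thermal_exit_altitudes(
    climbing_bouts, params: SegmentationParams | None = None
) -> list[float]:
    """Above-ground altitudes at the end of qualifying climbing bouts.

    Bouts whose end falls within the last ``burst_tail_exclusion_s``
    seconds of their GPS burst are excluded (the thermal may continue
    beyond the recording).
    """
    params = params or SegmentationParams()
    out = []
    for b in climbing_bouts:
        lead = (b.burst_end_time - b.end_time) / np.timedelta64(1, "s")
        if lead >= params.burst_tail_exclusion_s:
            out.append(float(b.end_altitude_agl))
    return out


def bouts_table(bouts) -> pd.DataFrame:
    """Tidy table of bouts (one row each) for export."""
    return pd.DataFrame([
        {
            "individual_id": b.individual_id,
            "kind": b.kind,
            "start_time": pd.Timestamp(b.start_time),
            "end_time": pd.Timestamp(b.end_time),
            "duration_s": b.duration_s,
            "mean_raw_climb_rate": b.mean_raw_climb_rate,
            "mean_ground_speed": b.mean_ground_speed,
            "end_altitude_agl": b.end_altitude_agl,
            "burst_start_time": pd.Timestamp(b.burst_start_time),
        }
        for b in bouts
    ])
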