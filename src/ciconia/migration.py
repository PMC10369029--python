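"""Daily and broad-scale migration metrics.

Implements the day-level bookkeeping (stopover vs migration days, main
migration flight, cross-country speed, daylength, daily wind support) and
the individual-level outcomes (migration distance and propensity, Sahara
crossing, wintering latitude, transit of the 47.5N-44N reference segment,
route straightness, survival) for soaring-gliding migrants tracked with
burst-mode GPS.

Conventions: a "day" is a UTC calendar date (the tags schedule in GMT);
the main migration flight of a day is the longest chain of
flight-containing bursts whose internal non-flight gaps do not exceed 60
minutes, which operationally excludes short morning/evening commuting
flights; segment membership is decided by each burst's final fix.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geodesic, solar
from .flightmetrics import daily_wind_support
from .io import GPSBurst, ValidationError


@dataclass
class MigrationParams:
    migration_day_min_km: float = 50.0
    propensity_min_km: float = 200.0
    sahara_min_km: float = 3000.0
    segment_lat_north: float = 47.5
    segment_lat_south: float = 44.0
    death_exclusion_days: float = 3.0
    release_exclusion_days: float = 5.0
    main_flight_max_gap_min: float = 60.0

    def validate(self) -> None:
        if not (self.sahara_min_km > self.propensity_min_km > self.migration_day_min_km):
            raise ValueError("thresholds must satisfy sahara > propensity > migration-day")


@dataclass
class ReleaseInfo:
    """Reference point for an individual's migration distance.

    For aviary-released birds the release location/date; for naturally
    fledged birds ``released=False`` and the first fix on/after 1 July of
    the tagging year serves as reference.
    """

    individual_id: str
    date: dt.date
    lat: float
    lon: float
    released: bool = True


@dataclass
class SegmentTransit:
    entry_t: pd.Timestamp
    exit_t: pd.Timestamp
    days_in_segment: float
    stopover_days_in_segment: int


@dataclass
class IndividualSummary:
    individual_id: str
    group: str | None
    reference_lat: float
    reference_lon: float
    southern_lat: float
    southern_lon: float
    southern_date: pd.Timestamp
    migration_distance_km: float
    migratory: bool
    crossed_sahara: bool
    wintering_latitude: float
    transit: SegmentTransit | None
    route_straightness: float
    alive_at_cutoff: bool | None
    excluded: bool
    exclusion_reason: str = ""
    extras: dict = field(default_factory=dict)


def _chains(flight_bursts: list[GPSBurst], max_gap_s: float) -> list[list[GPSBurst]]:
    chains: list[list[GPSBurst]] = []
    for b in flight_bursts:
        if chains and (b.start_time - chains[-1][-1].end_time) / np.timedelta64(1, "s") <= max_gap_s:
            chains[-1].append(b)
        else:
            chains.append([b])
    return chains


def daily_summaries(
    bursts: list[GPSBurst],
    flight_bouts_by_burst: dict[int, list] | list | None,
    params: MigrationParams | None = None,
) -> pd.DataFrame:
    """Per-individual, per-UTC-date summary table.

    ``flight_bouts_by_burst`` maps ``id(burst)`` -> flight bouts (or is a
    parallel list); bursts containing at least one flight bout make up the
    candidate migration flight. Days with fewer than two fixes get NaN
    displacement and are not classified.
    """
    params = params or MigrationParams()
    if isinstance(flight_bouts_by_burst, list):
        flight_bouts_by_burst = {
            id(b): fb for b, fb in zip(bursts, flight_bouts_by_burst)
        }
    flight_bouts_by_burst = flight_bouts_by_burst or {}

    by_ind_day: dict[tuple[str, dt.date], list[GPSBurst]] = {}
    for b in bursts:
        day = pd.Timestamp(b.start_time).date()
        by_ind_day.setdefault((b.individual_id, day), []).append(b)

    rows = []
    for (ind, day), bs in sorted(by_ind_day.items()):
        bs.sort(key=lambda b: b.start_time)
        lats = np.concatenate([b.lat for b in bs])
        lons = np.concatenate([b.lon for b in bs])
        n_fix = lats.size
        row: dict = {
            "individual_id": ind, "date": pd.Timestamp(day),
            "first_lat": lats[0], "first_lon": lons[0],
            "last_lat": lats[-1], "last_lon": lons[-1],
            "n_fixes": n_fix,
        }
        if n_fix < 2:
            row.update({
                "displacement_km": np.nan, "is_migration_day": pd.NA,
                "flight_time_h": np.nan, "daily_distance_km": np.nan,
                "cross_country_speed_ms": np.nan, "cross_country_speed_kmh": np.nan,
                "daylength_h": np.nan, "mean_wind_u": np.nan, "mean_wind_v": np.nan,
                "wind_support_ms": np.nan,
            })
            rows.append(row)
            continue

        disp_km = geodesic.distance(lats[0], lons[0], lats[-1], lons[-1]) / 1000.0
        row["displacement_km"] = disp_km
        row["daily_distance_km"] = disp_km
        row["is_migration_day"] = bool(disp_km > params.migration_day_min_km)

        try:
            row["daylength_h"] = solar.daylength_hours(
                day, lats[0], lons[0], lats[-1], lons[-1]
            )
        except solar.PolarLightError:
            row["daylength_h"] = np.nan

        flight_bursts = [b for b in bs if flight_bouts_by_burst.get(id(b))]
        row.update({
            "flight_time_h": np.nan, "cross_country_speed_ms": np.nan,
            "cross_country_speed_kmh": np.nan, "mean_wind_u": np.nan,
            "mean_wind_v": np.nan, "wind_support_ms": np.nan,
        })
        if flight_bursts:
            chains = _chains(flight_bursts, params.main_flight_max_gap_min * 60.0)
            main = max(
                chains,
                key=lambda c: (c[-1].end_time - c[0].start_time) / np.timedelta64(1, "s"),
            )
            span_s = (main[-1].end_time - main[0].start_time) / np.timedelta64(1, "s")
            if span_s > 0:
                f_lat, f_lon = main[0].lat[0], main[0].lon[0]
                l_lat, l_lon = main[-1].lat[-1], main[-1].lon[-1]
                dist_m = geodesic.distance(f_lat, f_lon, l_lat, l_lon)
                row["flight_time_h"] = span_s / 3600.0
                row["cross_country_speed_ms"] = dist_m / span_s
                row["cross_country_speed_kmh"] = dist_m / span_s * 3.6
                if main[0].wind_u is not None:
                    wu = float(np.nanmean(np.concatenate([b.wind_u for b in main])))
                    wv = float(np.nanmean(np.concatenate([b.wind_v for b in main])))
                    row["mean_wind_u"] = wu
                    row["mean_wind_v"] = wv
                    if dist_m > 0:
                        row["wind_support_ms"] = daily_wind_support(
                            f_lat, f_lon, l_lat, l_lon, wu, wv
                        )
        rows.append(row)
    return pd.DataFrame(rows)


def segment_transit(
    bursts: list[GPSBurst],
    daily: pd.DataFrame | None = None,
    params: MigrationParams | None = None,
) -> SegmentTransit | None:
    """Entry/exit of the reference latitude band for one individual.

    Entry is the end time of the first burst whose final fix lies at or
    south of the northern edge, provided an earlier burst ended north of
    it; exit is the end time of the first subsequent burst ending south of
    the southern edge. Returns None for individuals that never transit
    north-to-south. Stopover days count calendar days strictly inside the
    (entry, exit) interval classified by the displacement rule.
    """
    params = params or MigrationParams()
    bs = sorted(bursts, key=lambda b: b.start_time)
    if not bs:
        return None

    seen_north = False
    entry_t = exit_t = None
    for b in bs:
        lat_end = b.lat[-1]
        if entry_t is None:
            if lat_end > params.segment_lat_north:
                seen_north = True
            elif seen_north and lat_end <= params.segment_lat_north:
                entry_t = pd.Timestamp(b.end_time)
                if lat_end < params.segment_lat_south:  # jumped straight through
                    exit_t = pd.Timestamp(b.end_time)
                    break
        else:
            if lat_end < params.segment_lat_south:
                exit_t = pd.Timestamp(b.end_time)
                break
    if entry_t is None or exit_t is None:
        return None

    days = (exit_t - entry_t).total_seconds() / 86400.0
    stop = 0
    if daily is not None and len(daily):
        ind = bs[0].individual_id
        sub = daily[daily["individual_id"] == ind]
        for r in sub.itertuples(index=False):
            d = pd.Timestamp(r.date).date()
            if entry_t.date() < d < exit_t.date() and r.is_migration_day is False:
                stop += 1
    return SegmentTransit(entry_t, exit_t, days, stop)


def route_straightness(bursts: list[GPSBurst], transit: SegmentTransit) -> float:
    """Straight-line entry->exit distance over cumulative within-segment distance."""
    lats, lons, times = [], [], []
    for b in sorted(bursts, key=lambda b: b.start_time):
        t = pd.to_datetime(b.t)
        m = (t >= transit.entry_t) & (t <= transit.exit_t)
        lats.append(b.lat[m])
        lons.append(b.lon[m])
    lat = np.concatenate(lats)
    lon = np.concatenate(lons)
    if lat.size < 2:
        return np.nan
    straight = geodesic.distance(lat[0], lon[0], lat[-1], lon[-1])
    cumulative = geodesic.cumulative_distance(lat, lon)
    if cumulative == 0:
        return np.nan
    return float(straight / cumulative)


def migration_summary(
    bursts: list[GPSBurst],
    release: ReleaseInfo,
    params: MigrationParams | None = None,
    group: str | None = None,
    death_date: dt.date | None = None,
    survival_cutoff: dt.date | None = None,
    daily: pd.DataFrame | None = None,
) -> IndividualSummary:
    """Broad-scale outcome summary for one individual's track."""
    params = params or MigrationParams()
    if not bursts:
        raise ValueError("empty track")
    bs = sorted(bursts, key=lambda b: b.start_time)
    ind = bs[0].individual_id

    lat = np.concatenate([b.lat for b in bs])
    lon = np.concatenate([b.lon for b in bs])
    t = pd.to_datetime(np.concatenate([b.t for b in bs]))

    if release.released:
        ref_lat, ref_lon = release.lat, release.lon
    else:
        july1 = pd.Timestamp(dt.date(release.date.year, 7, 1))
        m = np.asarray(t >= july1)
        i0 = int(np.argmax(m)) if m.any() else 0
        ref_lat, ref_lon = lat[i0], lon[i0]

    # first-year window: reference date -> 30 June of the following year
    window_end = pd.Timestamp(dt.date(release.date.year + 1, 6, 30)) + pd.Timedelta(days=1)
    in_win = np.asarray(t < window_end)
    lat_w, lon_w, t_w = lat[in_win], lon[in_win], t[in_win]
    if lat_w.size == 0:
        lat_w, lon_w, t_w = lat, lon, t
    i_s = int(np.argmin(lat_w))
    southern_lat, southern_lon = float(lat_w[i_s]), float(lon_w[i_s])
    southern_date = pd.Timestamp(t_w[i_s])

    dist_km = geodesic.distance(ref_lat, ref_lon, southern_lat, southern_lon) / 1000.0
    migratory = dist_km > params.propensity_min_km
    crossed = dist_km > params.sahara_min_km

    excluded, reason = False, ""
    if death_date is not None:
        if (pd.Timestamp(death_date) - southern_date.normalize()).days < params.death_exclusion_days:
            excluded, reason = True, "death-window"
    if not excluded and release.released:
        if (southern_date.normalize() - pd.Timestamp(release.date)).days <= params.release_exclusion_days:
            excluded, reason = True, "release-window"

    transit = segment_transit(bs, daily, params)
    straightness = route_straightness(bs, transit) if transit else np.nan

    alive = None
    if survival_cutoff is not None:
        alive = death_date is None or death_date > survival_cutoff

    return IndividualSummary(
        individual_id=ind,
        group=group,
        reference_lat=float(ref_lat),
        reference_lon=float(ref_lon),
        southern_lat=southern_lat,
        southern_lon=southern_lon,
        southern_date=southern_date,
        migration_distance_km=float(dist_km),
        migratory=bool(migratory),
        crossed_sahara=bool(crossed),
        wintering_latitude=southern_lat,
        transit=transit,
        route_straightness=straightness,
        alive_at_cutoff=alive,
        excluded=excluded,
        exclusion_reason=reason,
    )


def summaries_table(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "individual_id": s.individual_id,
            "group": s.group,
            "migration_distance_km": s.migration_distance_km,
            "migratory": s.migratory,
            "crossed_sahara": s.crossed_sahara,
            "wintering_latitude": s.wintering_latitude,
            "segment_entry_t": s.transit.entry_t if s.transit else pd.NaT,
            "segment_exit_t": s.transit.exit_t if s.transit else pd.NaT,
            "days_in_segment": s.transit.days_in_segment if s.transit else np.nan,
            "stopover_days_in_segment": (
                s.transit.stopover_days_in_segment if s.transit else np.nan
            ),
            "route_straightness": s.route_straightness,
            "alive_at_cutoff": s.alive_at_cutoff,
            "excluded": s.excluded,
            "exclusion_reason": s.exclusion_reason,
        })
    return pd.DataFrame(rows)


def survival_series(
    release_dates,
    death_dates,
    cutoff: dt.date,
) -> tuple[pd.Series, float]:
    """Proportion of the cohort alive over time, and the value at cutoff.

    ``death_dates`` holds one entry per individual (None = survived; birds
    taken into care count as dead at capture, encoded by the caller).
    Returns a right-continuous step series indexed by event date, starting
    at 1.0, and the proportion alive at ``cutoff``. A death before its
    release raises :class:`ValidationError`.
    """
    release_dates = list(release_dates)
    death_dates = list(death_dates)
    if len(release_dates) != len(death_dates):
        raise ValidationError("release and death date lists differ in length")
    n = len(release_dates)
    if n == 0:
        raise ValidationError("empty cohort")
    for r, d in zip(release_dates, death_dates):
        if d is not None and pd.Timestamp(d) < pd.Timestamp(r):
            raise ValidationError("death before release")

    deaths = sorted(pd.Timestamp(d) for d in death_dates if d is not None)
    start = min(pd.Timestamp(r) for r in release_dates)
    idx = [start] + deaths
    vals = [1.0] + [1.0 - (k + 1) / n for k in range(len(deaths))]
    series = pd.Series(vals, index=pd.DatetimeIndex(idx)).groupby(level=0).min()

    cut = pd.Timestamp(cutoff)
    alive = 1.0 - sum(1 for d in deaths if d <= cut) / n
    return series, float(alive)


def altitude_flap_profile(odba_records: pd.DataFrame, bin_m: float = 100.0) -> pd.DataFrame:
    """Mean/median ODBA of gliding-labelled ACC bursts by altitude-AGL bin.

    Flapping concentrates at low altitude when birds fight to stay
    airborne between thermals, so the low bins show elevated ODBA.
    """
    glide = odba_records[odba_records["behaviour"] == "gliding"].dropna(subset=["altitude_agl"])
    if glide.empty:
        return pd.DataFrame(columns=["alt_bin_low", "alt_bin_high", "n", "mean_odba", "median_odba"])
    bins = np.floor(glide["altitude_agl"] / bin_m).astype(int)
    out = []
    for b, sub in glide.groupby(bins):
        out.append({
            "alt_bin_low": b * bin_m,
            "alt_bin_high": (b + 1) * bin_m,
            "n": len(sub),
            "mean_odba": sub["odba"].mean(),
            "median_odba": sub["odba"].median(),
        })
    return pd.DataFrame(out).sort_values("alt_bin_low").reset_index(drop=True)
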