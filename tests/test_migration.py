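import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ciconia import geodesic, io, migration


def track_bursts(points, individual="m1"):
    """Single-fix bursts from (timestamp, lat, lon) tuples."""
    bursts = []
    for ts, lat, lon in points:
        b = io.GPSBurst(
            individual_id=individual,
            t=np.array([pd.Timestamp(ts).to_datetime64()], dtype="datetime64[ns]"),
            lon=np.array([float(lon)]), lat=np.array([float(lat)]),
            hae=np.array([0.0]), ground_elev=np.array([0.0]),
        )
        io.derive_kinematics(b)
        bursts.append(b)
    return bursts


def km_north_of(lat, km):
    m_lat, _ = geodesic.meters_per_degree(lat)
    return lat + km * 1000.0 / m_lat


class TestDailySummaries:
    def test_60km_day_is_migration_day(self):
        lat2 = km_north_of(48.0, -60.0)
        bursts = track_bursts([("2020-08-01 05:00:00", 48.0, 9.0),
                               ("2020-08-01 18:00:00", lat2, 9.0)])
        daily = migration.daily_summaries(bursts, None)
        assert daily["displacement_km"].iloc[0] == pytest.approx(60.0, rel=1e-3)
        assert bool(daily["is_migration_day"].iloc[0]) is True

    def test_just_under_50km_is_stopover(self):
        lat2 = km_north_of(48.0, -49.9)
        bursts = track_bursts([("2020-08-01 05:00:00", 48.0, 9.0),
                               ("2020-08-01 18:00:00", lat2, 9.0)])
        daily = migration.daily_summaries(bursts, None)
        assert bool(daily["is_migration_day"].iloc[0]) is False

    def test_single_fix_day_unclassified(self):
        bursts = track_bursts([("2020-08-01 05:00:00", 48.0, 9.0)])
        daily = migration.daily_summaries(bursts, None)
        assert np.isnan(daily["displacement_km"].iloc[0])

    def _flight_day(self, morning_commute=False):
        """Bursts every 15 min moving south at 8 m/s for 6 h; positions keep
        advancing between bursts (the bird flies continuously)."""
        t0 = pd.Timestamp("2020-08-01 08:00:00")
        start_lat, lon = 48.0, 9.0
        m_lat, _ = geodesic.meters_per_degree(start_lat)
        bursts = []
        for k in range(24):  # 6 h of 15-min slots
            offset = k * 900
            tt = t0 + pd.Timedelta(seconds=offset)
            sec = offset + np.arange(600)
            lat = start_lat - 8.0 * sec / m_lat
            b = io.GPSBurst(
                individual_id="m1",
                t=(tt.to_datetime64() + (np.arange(600) * 1e9).astype("timedelta64[ns]")),
                lon=np.full(600, lon), lat=lat,
                hae=np.full(600, 500.0), ground_elev=np.zeros(600),
            )
            bursts.append(io.derive_kinematics(b))
        if morning_commute:
            tt = t0 - pd.Timedelta(hours=3)
            lat = start_lat + 5.0 * np.arange(300) / m_lat
            b = io.GPSBurst(
                individual_id="m1",
                t=(tt.to_datetime64() + (np.arange(300) * 1e9).astype("timedelta64[ns]")),
                lon=np.full(300, lon), lat=lat,
                hae=np.full(300, 50.0), ground_elev=np.zeros(300),
            )
            bursts.insert(0, io.derive_kinematics(b))
        from ciconia import segmentation as seg
        flight_map = {id(b): seg.detect_flight(b, seg.SegmentationParams()) for b in bursts}
        return bursts, flight_map

    def test_cross_country_speed_matches_construction(self):
        bursts, flight_map = self._flight_day()
        daily = migration.daily_summaries(bursts, flight_map)
        # 8 m/s for the whole main flight, zero wind annotation absent
        assert daily["cross_country_speed_ms"].iloc[0] == pytest.approx(8.0, rel=0.01)
        assert daily["cross_country_speed_kmh"].iloc[0] == pytest.approx(28.8, rel=0.01)
        # span of the 24-slot chain: 23*900 s + 600 s
        assert daily["flight_time_h"].iloc[0] == pytest.approx((23 * 900 + 599) / 3600, rel=0.01)

    def test_morning_commute_excluded_from_main_flight(self):
        bursts, flight_map = self._flight_day(morning_commute=True)
        daily = migration.daily_summaries(bursts, flight_map)
        # the 3-h gap detaches the commute; flight time unchanged
        assert daily["flight_time_h"].iloc[0] == pytest.approx((23 * 900 + 599) / 3600, rel=0.01)


class TestSegmentTransit:
    def _southbound(self, km_per_day=300.0, start_lat=48.0, days=4.0, step_h=1.0):
        pts = []
        t = pd.Timestamp("2020-08-20 00:00:00")
        lat = start_lat
        n = int(days * 24 / step_h)
        for k in range(n):
            pts.append((t, lat, 9.0))
            t = t + pd.Timedelta(hours=step_h)
            m_lat, _ = geodesic.meters_per_degree(lat)
            lat = lat - km_per_day * 1000.0 / 24.0 * step_h / m_lat
        return track_bursts(pts)

    def test_transit_duration_matches_arc_length(self):
        bursts = self._southbound(300.0)
        tr = migration.segment_transit(bursts)
        assert tr is not None
        arc_km = geodesic.distance(47.5, 9.0, 44.0, 9.0) / 1000.0
        assert tr.days_in_segment == pytest.approx(arc_km / 300.0, abs=0.1)

    def test_track_starting_inside_segment_not_transited(self):
        bursts = self._southbound(300.0, start_lat=47.0)
        assert migration.segment_transit(bursts) is None

    def test_oscillation_entry_at_first_southward_end(self):
        pts = [("2020-08-20 00:00:00", 48.0, 9.0),
               ("2020-08-20 06:00:00", 47.4, 9.0),   # first end-fix inside
               ("2020-08-20 12:00:00", 47.8, 9.0),   # bounces back north
               ("2020-08-20 18:00:00", 47.2, 9.0),
               ("2020-08-21 12:00:00", 43.9, 9.0)]
        bursts = track_bursts(pts)
        tr = migration.segment_transit(bursts)
        assert tr.entry_t == pd.Timestamp("2020-08-20 06:00:00")
        assert tr.exit_t == pd.Timestamp("2020-08-21 12:00:00")

    def test_never_entering_from_north(self):
        bursts = track_bursts([("2020-08-20 00:00:00", 43.0, 9.0),
                               ("2020-08-21 00:00:00", 42.0, 9.0)])
        assert migration.segment_transit(bursts) is None


class TestStraightness:
    def test_straight_track_is_one(self):
        bursts = TestSegmentTransit()._southbound(300.0)
        tr = migration.segment_transit(bursts)
        s = migration.route_straightness(bursts, tr)
        assert s == pytest.approx(1.0, abs=1e-3)

    def test_dog_leg_strictly_below_one(self):
        pts = [("2020-08-20 00:00:00", 48.0, 9.0),
               ("2020-08-20 06:00:00", 47.0, 9.0),
               ("2020-08-20 12:00:00", 46.0, 12.0),  # detour east
               ("2020-08-20 18:00:00", 45.0, 9.0),
               ("2020-08-21 00:00:00", 43.8, 9.0)]
        bursts = track_bursts(pts)
        tr = migration.segment_transit(bursts)
        s = migration.route_straightness(bursts, tr)
        assert s < 0.95


class TestMigrationSummary:
    def _track_reaching(self, km_south, individual="m1", start="2020-08-20"):
        lat2 = km_north_of(48.0, -km_south)
        return track_bursts([
            (f"{start} 06:00:00", 48.0, 9.0),
            ("2020-09-10 06:00:00", lat2, 9.0),
            ("2020-12-01 06:00:00", lat2, 9.0),
        ], individual=individual)

    def _release(self, date=dt.date(2020, 8, 15)):
        return migration.ReleaseInfo("m1", date, 48.0, 9.0, released=True)

    def test_propensity_and_sahara_flags_monotone_in_distance(self):
        flags = []
        for km in (150.0, 250.0, 3500.0):
            s = migration.migration_summary(self._track_reaching(km), self._release())
            flags.append((s.migratory, s.crossed_sahara))
            assert s.migration_distance_km == pytest.approx(km, rel=0.01)
        assert flags == [(False, False), (True, False), (True, True)]

    def test_wintering_latitude_is_southernmost(self):
        s = migration.migration_summary(self._track_reaching(500.0), self._release())
        assert s.wintering_latitude == pytest.approx(km_north_of(48.0, -500.0), abs=1e-6)

    def test_death_window_exclusion(self):
        s = migration.migration_summary(
            self._track_reaching(500.0), self._release(),
            death_date=dt.date(2020, 9, 12),  # southernmost on 10 Sep, death 2 d later
        )
        assert s.excluded and s.exclusion_reason == "death-window"

    def test_release_window_exclusion(self):
        bursts = track_bursts([
            ("2020-08-16 06:00:00", 48.0, 9.0),
            ("2020-08-18 06:00:00", km_north_of(48.0, -300.0), 9.0),
            ("2020-10-01 06:00:00", 48.0, 9.0),  # returns north
        ])
        s = migration.migration_summary(bursts, self._release(dt.date(2020, 8, 15)))
        assert s.excluded and s.exclusion_reason == "release-window"

    def test_naturally_timed_reference_is_first_july_fix(self):
        bursts = track_bursts([
            ("2020-06-20 06:00:00", 49.0, 9.0),
            ("2020-07-02 06:00:00", 48.0, 9.0),
            ("2020-09-10 06:00:00", km_north_of(48.0, -400.0), 9.0),
        ])
        rel = migration.ReleaseInfo("m1", dt.date(2020, 7, 1), np.nan, np.nan, released=False)
        s = migration.migration_summary(bursts, rel)
        assert s.reference_lat == pytest.approx(48.0)
        assert s.migration_distance_km == pytest.approx(400.0, rel=0.01)


class TestSurvival:
    def test_no_deaths_constant_one(self):
        rel = [dt.date(2020, 8, 1)] * 5
        series, alive = migration.survival_series(rel, [None] * 5, dt.date(2021, 6, 30))
        assert alive == 1.0
        assert (series == 1.0).all()

    def test_forty_birds_seventeen_deaths(self):
        rel = [dt.date(2020, 9, 15)] * 40
        deaths = [dt.date(2020, 10, 1 + k % 28) for k in range(17)] + [None] * 23
        _, alive = migration.survival_series(rel, deaths, dt.date(2021, 6, 30))
        assert alive == pytest.approx(23 / 40)

    def test_step_function_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(12)
        rel = [dt.date(2020, 8, 1)] * 30
        offsets = rng.integers(1, 250, size=18)
        deaths = [dt.date(2020, 8, 1) + dt.timedelta(days=int(o)) for o in offsets]
        deaths += [None] * 12
        series, _ = migration.survival_series(rel, deaths, dt.date(2021, 6, 30))
        death_ts = sorted(pd.Timestamp(d) for d in deaths if d is not None)
        for when, value in series.items():
            ecdf = sum(1 for d in death_ts if d <= when) / 30
            assert value == pytest.approx(1.0 - ecdf)

    def test_death_before_release_rejected(self):
        with pytest.raises(io.ValidationError):
            migration.survival_series(
                [dt.date(2020, 8, 1)], [dt.date(2020, 7, 1)], dt.date(2021, 6, 30)
            )


class TestAltitudeFlapProfile:
    def test_low_altitude_bin_has_higher_odba(self):
        rng = np.random.default_rng(3)
        n = 200
        alt = np.concatenate([rng.uniform(0, 500, n), rng.uniform(500, 1500, n)])
        odba = np.concatenate([rng.normal(4.0, 0.5, n), rng.normal(1.0, 0.3, n)])
        df = pd.DataFrame({
            "individual_id": "x", "t": pd.Timestamp("2020-08-01"),
            "odba": odba, "behaviour": "gliding", "altitude_agl": alt,
        })
        prof = migration.altitude_flap_profile(df, bin_m=500.0)
        below = prof.loc[prof["alt_bin_low"] == 0.0, "mean_odba"].iloc[0]
        above = prof.loc[prof["alt_bin_low"] == 500.0, "mean_odba"].iloc[0]
        assert below > above

    def test_empty_input_gives_empty_table(self):
        df = pd.DataFrame(columns=["individual_id", "t", "odba", "behaviour", "altitude_agl"])
        assert migration.altitude_flap_profile(df).empty

    def test_days_in_segment_bounds_stopover_days(self, cohort_run):
        _, rr = cohort_run
        sub = rr.individuals.dropna(subset=["days_in_segment"])
        assert (sub["days_in_segment"] >= sub["stopover_days_in_segment"] - 1e-9).all()
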