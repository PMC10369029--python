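import numpy as np
import pytest

from ciconia import segmentation as seg

from conftest import make_burst
from oracles import bout_runs


def unsmoothed_params(**kw):
    """Params with a 1-sample window so run/gap logic is tested in isolation."""
    return seg.SegmentationParams(smooth_window_s=1.0, **kw)


class TestSmooth:
    def test_constant_series_unchanged(self):
        out = seg.smooth(np.full(100, 3.7), 15.0, 1.0)
        np.testing.assert_allclose(out, 3.7)

    def test_impulse_spreads_to_window_mean(self):
        x = np.zeros(101)
        x[50] = 15.0
        out = seg.smooth(x, 15.0, 1.0)
        assert out[50] == pytest.approx(1.0)
        assert out[57] == pytest.approx(1.0)
        assert out[58] == 0.0

    def test_linear_ramp_identity_away_from_edges(self):
        x = np.arange(100, dtype=float)
        out = seg.smooth(x, 15.0, 1.0)
        np.testing.assert_allclose(out[7:-7], x[7:-7], atol=1e-9)

    def test_edges_truncate_not_pad(self):
        x = np.arange(100, dtype=float)
        out = seg.smooth(x, 15.0, 1.0)
        # first value averages samples 0..7 only
        assert out[0] == pytest.approx(np.mean(x[:8]))

    def test_empty_series(self):
        assert seg.smooth([], 15.0, 1.0).size == 0


class TestDetectFlight:
    def test_constant_speed_whole_burst(self):
        b = make_burst(speeds=np.full(599, 3.0))
        bouts = seg.detect_flight(b, seg.SegmentationParams())
        assert len(bouts) == 1
        assert bouts[0].start_idx == 0 and bouts[0].end_idx == 598
        assert bouts[0].duration_s == pytest.approx(599.0)

    def test_short_run_below_minimum_discarded(self):
        speeds = np.zeros(100)
        speeds[40:50] = 3.0  # only 10 s
        b = make_burst(speeds=speeds)
        assert seg.detect_flight(b, unsmoothed_params()) == []

    def test_gap_rule_merges_44s_bout(self):
        speeds = np.concatenate([np.zeros(20), np.full(20, 3.0), np.full(4, 1.0),
                                 np.full(20, 3.0), np.zeros(20)])
        b = make_burst(speeds=speeds)
        bouts = seg.detect_flight(b, unsmoothed_params())
        assert len(bouts) == 1
        assert bouts[0].duration_s == pytest.approx(44.0)

    def test_six_second_interruption_splits(self):
        speeds = np.concatenate([np.full(20, 3.0), np.full(6, 1.0), np.full(20, 3.0)])
        b = make_burst(speeds=speeds)
        bouts = seg.detect_flight(b, unsmoothed_params())
        assert len(bouts) == 2

    def test_raising_threshold_never_increases_flight_time(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            speeds = np.abs(rng.normal(2.5, 1.5, 200))
            b = make_burst(speeds=speeds)
            prev = None
            for thr in (1.5, 2.5, 3.5, 4.5):
                p = seg.SegmentationParams(flight_speed_min=thr)
                total = sum(fb.duration_s for fb in seg.detect_flight(b, p))
                if prev is not None:
                    assert total <= prev + 1e-9
                prev = total


class TestClimbGlide:
    def test_climb_then_glide_with_raw_means(self):
        climbs = np.concatenate([np.full(60, 2.0), np.full(120, -1.5)])
        b = make_burst(speeds=np.full(180, 5.0), climbs=climbs)
        p = seg.SegmentationParams()
        fb = seg.detect_flight(b, p)[0]
        climbing, gliding = seg.classify_climb_glide(b, fb, p)
        assert len(climbing) == 1 and len(gliding) == 1
        assert climbing[0].mean_raw_climb_rate == pytest.approx(2.0, abs=0.05)
        assert gliding[0].mean_raw_climb_rate == pytest.approx(-1.5, abs=0.05)
        assert climbing[0].duration_s >= 45.0
        assert gliding[0].duration_s >= 105.0

    def test_dead_zone_yields_no_bouts(self):
        b = make_burst(speeds=np.full(120, 5.0), climbs=np.full(120, 0.1))
        p = seg.SegmentationParams()
        fb = seg.detect_flight(b, p)[0]
        climbing, gliding = seg.classify_climb_glide(b, fb, p)
        assert climbing == [] and gliding == []

    def test_dead_zone_interruption_merges(self):
        climbs = np.concatenate([np.full(20, 2.0), np.full(4, 0.1), np.full(20, 2.0)])
        b = make_burst(speeds=np.full(44, 5.0), climbs=climbs)
        p = unsmoothed_params(bout_min_s=15.0)
        fb = seg.detect_flight(b, p)[0]
        climbing, _ = seg.classify_climb_glide(b, fb, p)
        assert len(climbing) == 1
        assert climbing[0].duration_s == pytest.approx(44.0)

    def test_boundary_senses(self):
        # exactly 2.5 m/s counts as flight; exactly 0.2 is not climbing;
        # exactly 0.0 is not gliding. Derived arrays are set directly so
        # the threshold comparison sees the exact boundary values.
        b = make_burst(speeds=np.full(60, 5.0), climbs=np.zeros(60))
        b.ground_speed = np.full(60, 2.5)
        b.climb_rate = np.full(60, 0.2)
        p = unsmoothed_params()
        flight = seg.detect_flight(b, p)
        assert len(flight) == 1
        climbing, gliding = seg.classify_climb_glide(b, flight[0], p)
        assert climbing == [] and gliding == []
        b.climb_rate = np.full(60, 0.0)
        climbing, gliding = seg.classify_climb_glide(b, flight[0], p)
        assert climbing == [] and gliding == []


class TestThermalExits:
    def _climb_ending(self, seconds_before_end, alt=800.0):
        n = 200
        end_idx = n - 2 - int(seconds_before_end)
        climbs = np.zeros(n - 1)
        climbs[:end_idx + 1] = 2.0
        b = make_burst(speeds=np.full(n - 1, 5.0), climbs=climbs, hae0=alt - 2.0 * (end_idx + 1))
        p = unsmoothed_params()
        fb = seg.detect_flight(b, p)[0]
        climbing, _ = seg.classify_climb_glide(b, fb, p)
        return climbing, p

    def test_exit_far_from_burst_end_included(self):
        climbing, p = self._climb_ending(100)
        exits = seg.thermal_exit_altitudes(climbing, p)
        assert len(exits) == 1
        assert exits[0] == pytest.approx(800.0, abs=1.0)

    def test_exit_in_last_five_seconds_excluded(self):
        climbing, p = self._climb_ending(3)
        assert seg.thermal_exit_altitudes(climbing, p) == []


class TestBruteForceOracle:
    """Randomised equivalence with an independent run/gap/min-length scan."""

    @pytest.mark.parametrize("case_seed", range(40))
    def test_flight_bouts_equal_oracle(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        n = int(rng.integers(5, 100))
        speeds = rng.choice([0.5, 3.5], size=n, p=[0.4, 0.6])
        b = make_burst(speeds=speeds)
        p = unsmoothed_params()
        got = [(fb.start_idx, fb.end_idx) for fb in seg.detect_flight(b, p)]
        want = bout_runs(list(speeds >= 2.5), dt=1.0, min_s=15.0, gap_s=5.0)
        assert got == want

    @pytest.mark.parametrize("case_seed", range(40))
    def test_climb_glide_bouts_equal_oracle(self, case_seed):
        rng = np.random.default_rng(2000 + case_seed)
        n = int(rng.integers(20, 100))
        climbs = rng.choice([-1.5, 0.1, 2.0], size=n, p=[0.35, 0.2, 0.45])
        b = make_burst(speeds=np.full(n, 5.0), climbs=climbs)
        p = unsmoothed_params()
        flight = seg.detect_flight(b, p)
        if not flight:
            return
        fb = flight[0]
        climbing, gliding = seg.classify_climb_glide(b, fb, p)
        raw = b.climb_rate
        lo, hi = fb.start_idx, fb.end_idx
        cmask = [bool(lo <= i <= hi and raw[i] > 0.2) for i in range(n)]
        gmask = [bool(lo <= i <= hi and raw[i] < 0.0) for i in range(n)]
        assert [(x.start_idx, x.end_idx) for x in climbing] == bout_runs(cmask, forbid=gmask)
        assert [(x.start_idx, x.end_idx) for x in gliding] == bout_runs(gmask, forbid=cmask)


class TestPartitionInvariants:
    def test_climb_glide_disjoint_and_within_flight(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 300
            speeds = np.abs(rng.normal(4.0, 2.0, n))
            climbs = rng.normal(0.3, 1.5, n)
            b = make_burst(speeds=speeds, climbs=climbs)
            p = seg.SegmentationParams()
            flight, climbing, gliding = seg.segment_burst(b, p)
            fmask = np.zeros(n, dtype=bool)
            for fb in flight:
                fmask[fb.start_idx:fb.end_idx + 1] = True
            cmask = np.zeros(n, dtype=bool)
            for cb in climbing:
                cmask[cb.start_idx:cb.end_idx + 1] = True
            gmask = np.zeros(n, dtype=bool)
            for gb in gliding:
                gmask[gb.start_idx:gb.end_idx + 1] = True
            assert not (cmask & gmask).any()
            assert (cmask <= fmask).all() and (gmask <= fmask).all()
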