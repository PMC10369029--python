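# ciconia

Soaring–gliding migration analysis for burst-mode biologging data.

Juvenile white storks (*Ciconia ciconia*) and other large soaring migrants
are tracked with solar GPS–ACC loggers that record a position every 15 min
inside a 02:00–20:00 GMT duty window — a single fix when the bird is
stationary, a 10-min burst at 1 Hz when it flies — followed by a
four-second tri-axial accelerometer burst at 10 Hz. `ciconia` turns that
raw stream into the quantities movement ecologists compare between study
groups:

- **flight-bout segmentation** inside each GPS burst: flight whenever the
  15 s running-mean ground speed is ≥ 2.5 m s⁻¹; within flight, climbing
  (smoothed climb rate > 0.2 m s⁻¹) vs gliding (< 0 m s⁻¹), with a 15 s
  minimum bout length and ≤ 5 s interruptions;
- **thermalling performance**: raw climbing rates per bout and the
  altitude above ground at which a bird leaves each thermal;
- **ODBA** (overall dynamic body acceleration), the flapping-effort proxy
  `ODBA = Σ_axis mean_t |a(t) − ā|`, with behaviour assigned from the end
  of the preceding GPS burst;
- **wind decomposition** of annotated U/V winds into wind support,
  crosswind and airspeed relative to the ground track;
- **daily and broad-scale migration metrics**: migration vs stopover days
  (50 km displacement rule), cross-country speed, daylength between
  sunrise at the first and sunset at the last location, migration distance
  and propensity (200 km), Sahara crossing (3000 km), wintering latitude,
  transit of the 47.5°N–44°N reference segment, route straightness,
  first-year survival;
- **exact group statistics**: an r×c Fisher exact test of independence by
  full enumeration of the fixed-margin fibre, pairwise Fisher and Wilcoxon
  rank-sum tests with Benjamini–Hochberg FDR adjustment, Kruskal–Wallis.

A bundled synthetic generator (`ciconia.simulate`) produces ground-truth
labelled GPS + ACC cohorts with the same duty cycle from an alternating
thermalling/gliding state machine, so the whole pipeline is testable
end-to-end against known parameters. All geodesic computation is on the
WGS84 ellipsoid; sunrise/sunset use standard NOAA solar geometry.

## Worked example

Simulate one bird from the "delayed" study condition (weak late-season
thermals: mean climb rate 1.5 m s⁻¹, thermal exits around 650 m) and
recover its flight parameters from the raw fixes alone:

```python
import numpy as np
from ciconia import simulate, io, segmentation as seg

cfg = simulate.default_config(seed=42, n_individuals_per_group=1)
gps, acc, labels = simulate.simulate_individual(cfg, "delayed", "delayed-01")

bursts = [io.derive_kinematics(b) for b in io.assemble_bursts(gps)]
climbs, glides = [], []
for b in bursts:
    _, c, g = seg.segment_burst(b, seg.SegmentationParams())
    climbs += c; glides += g

rates = np.concatenate([[x.mean_raw_climb_rate] * x.n_fixes for x in climbs])
exits = seg.thermal_exit_altitudes(climbs, seg.SegmentationParams())
print(f"climbing bouts: {len(climbs)}   gliding bouts: {len(glides)}")
print(f"mean climbing rate: {rates.mean():.2f} m/s")
print(f"mean thermal-exit altitude: {np.mean(exits):.0f} m AGL  (n={len(exits)})")
```

```
climbing bouts: 81   gliding bouts: 106
mean climbing rate: 1.49 m/s
mean thermal-exit altitude: 646 m AGL  (n=61)
```

The segmentation recovers the generator's parameters (1.5 m s⁻¹, 650 m)
from five simulated migration days. The exact tests work on plain count
tables — e.g. migration propensity (migratory/resident) of three cohorts:

```bash
$ ciconia stats --table propensity.csv    # rows: 23/0, 12/0, 15/17
{
  "fisher_p": 7.5206639452067e-07,
  "pairwise": { "naturally_timed vs delayed": {"p_adj": 3.59e-05}, ... }
}
```

The full pipeline (simulate → read → segment → ODBA → daily/individual
summaries → group stats, all stages logged to a manifest) runs as:

```bash
ciconia all --seed 1 --out run1           # or: ciconia simulate / segment / ...
```

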