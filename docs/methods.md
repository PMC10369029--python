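# Methods

This note documents the models, conventions and numerical choices behind
`ciconia`, and what the synthetic generator does and does not emulate.

## Data model

A *GPS burst* is a contiguous 1 Hz block of fixes; bursts are
reconstructed purely from time gaps (default threshold 30 s — any value
between the 1 s fix interval and the 15 min schedule period gives the
same result, so the choice is uncritical). Derived kinematics are
per-pair quantities aligned to the later fix: ground speed is the WGS84
geodesic step distance over the time step; climb rate is the difference
in height above ellipsoid over the time step; altitude above ground is
height above ellipsoid minus the per-fix ground-elevation column. Any
geoid correction is assumed to be folded into the supplied
ground-elevation column upstream; the package does not apply one. All
timestamps are UTC throughout; "days" are UTC calendar dates (the tags
schedule in GMT), which avoids timezone tables at the cost of a bird's
biological day straddling midnight only in pathological cases.

Geodesics use a vectorised Vincenty inverse solution on WGS84
(cross-checked in the test suite against R `geosphere`'s Karney
implementation and a spherical haversine oracle). Sunrise/sunset use the
standard NOAA solar-position equations with the sun centre at −0.833°;
polar day/night raises an error and flags the day rather than guessing.

## Segmentation

Smoothing is a centred running mean over an odd number of samples
(15 s at 1 Hz); at burst edges the window truncates to the available
samples rather than padding — no fabricated data. Flight bouts are
maximal runs with smoothed ground speed ≥ 2.5 m s⁻¹; climbing and gliding
use the smoothed climb rate with thresholds > 0.2 and < 0 m s⁻¹
(boundary senses encoded exactly; rates in the [0, 0.2] dead zone belong
to neither class). Runs of the same kind separated by at most 5 s of
interruption are merged **before** the 15 s minimum-length rule is
applied — the only reading under which a 20 s + 4 s + 20 s pattern yields
the single 44 s bout both clauses imply. One refinement: for climbing and
gliding, a gap containing any sample of the *opposite* class terminates
the bout instead of merging across it. Dead-zone wobbles therefore
interrupt, opposite-class excursions end the bout; without this rule,
rapidly alternating series could produce overlapping climbing and gliding
bouts, and the disjointness of the two classes is an invariant the rest
of the pipeline (behaviour assignment, bout statistics) relies on. Bout
summaries (climbing rate, sinking speed) average the **raw**, not
smoothed, climb rates. Thermal-exit altitudes take the end altitude of
climbing bouts that do not end in the final 5 s of their burst, since a
climb still in progress at the end of a recording says nothing about
where the bird left the thermal.

## Flight metrics

ODBA is computed per ACC burst after linear per-axis calibration
((raw − offset) × gain → m s⁻²) as the sum over axes of the mean absolute
deviation from the axis mean. It is translation-invariant and scales
linearly with the signal — both are asserted as properties. Behaviour
is attached to each ACC burst from the bout containing the final fix of
the immediately preceding GPS burst of the same bird (no further back
than 20 min), "other" when no climbing or gliding bout contains it.

Wind decomposition projects the annotated wind vector onto the ground
track: support = (w·g)/|g| (positive tailwind), crosswind =
√(|w|² − support²) (magnitude only), airspeed =
√((|g| − support)² + crosswind²). Daily wind support projects the
flight-time-averaged wind onto the initial geodesic bearing from the
first to the last location of the day's main migration flight — at the
sub-1000 km daily scale the initial bearing is an adequate stand-in for
the straight-line direction.

## Daily and broad-scale metrics

A day is a migration day when the geodesic displacement between its first
and last fix exceeds 50 km, otherwise a stopover day. The *main
migration flight* is the longest chain of flight-containing bursts whose
internal non-flight gaps stay within 60 min; this operationalises the
exclusion of short morning/evening commuting flights (the gap length is
configurable; the convention is this package's, chosen because commuting
flights sit hours away from the main flight while thermalling pauses are
minutes). Daily flight time is that chain's span; cross-country speed is
the geodesic distance between the chain's first and last fix divided by
the span, reported in both m s⁻¹ and km h⁻¹.

Migration distance is the geodesic distance from the reference point
(release location for aviary-released birds, first fix on/after 1 July
otherwise) to the southernmost location inside the first-year window
(reference date to 30 June of the following year). Thresholds: > 200 km
migratory, > 3000 km Sahara crossing. Birds whose southernmost point
falls within 3 days before death or 5 days after release are flagged
excluded (migration plausibly unfinished). Wintering latitude is the
southernmost latitude in the window.

Segment transit (47.5°N → 44°N): entry is the end time of the first burst
whose final fix lies at or south of 47.5°N after an earlier burst ended
north of it; exit is the first subsequent burst ending south of 44°N;
birds that never make the north-to-south passage are excluded. Days in
segment are fractional (exit − entry in days); stopover days count
calendar days strictly inside the interval under the 50 km rule. Route
straightness is entry-to-exit geodesic distance divided by the cumulative
fix-to-fix distance inside the segment, so 1 is a perfectly straight
passage. Survival is the right-continuous step function
1 − ECDF(death dates) starting at 1.0 at release; birds taken into care
count as dead at capture.

## Statistics

The r×c Fisher exact test defines its two-sided p-value by
probability-mass ordering: the total multivariate-hypergeometric
probability of all tables with the observed margins whose probability
does not exceed the observed table's (relative tie tolerance 1e−12, so
symmetric tables count their mirror images). The fibre is enumerated
recursively row by row under the remaining column margins — a few hundred
tables for the 3×2 cohort comparisons used here, exact and fast. Tables
with a zero row or column margin are degenerate and return p = 1.
Kruskal–Wallis (tie-corrected, chi-squared approximation) and
Mann–Whitney rank-sum tests delegate to scipy (exact enumeration for
tie-free samples of ≤ 25, normal approximation with tie correction
otherwise); Benjamini–Hochberg adjustment delegates to statsmodels.
Mixed-model ANOVAs (Kenward–Roger, Tukey HSD, AIC comparison) are out of
scope by design: the pipeline exports tidy per-day and per-individual
tables for external fitting.

## Synthetic generator

The generator emulates the tag duty cycle (15 min schedule, 10-min 1 Hz
bursts in flight, single fixes when stationary, 4 s / 10 Hz ACC directly
after each GPS event, nothing outside 02:00–20:00 GMT) and the
statistical structure the analysis assumes: migration days built from an
alternating state machine of circling climbs (radius 30 m, tangential
speed 8 m s⁻¹, vertical rate = group mean + N(0, 0.3) per second, circle
centre drifting with the wind, exit altitude drawn per thermal) and
straight glides (airspeed along the target heading plus wind advection,
constant sink, heading wobble σ = 4°), with flapping below 500 m AGL
encoded as a sinusoidal heave-axis component and a hidden truth label
(stationary/flap/climb/glide) on every fix. Stopover days are a per-day
Bernoulli draw; wind is constant within a day, drawn around the group
mean with σ = 0.8 m s⁻¹ per component. Measurement noise is independent
Gaussian per fix (position noise equivalent to σ = 0.5 m s⁻¹ in 1 Hz
ground speed, σ = 1 m in altitude) — the simplest model that stresses the
15 s smoothing window.

The three default groups encode a delayed-release experiment's contrasts,
with cohort-level expectations at field-realistic values: naturally timed
(climb 2.2 m s⁻¹, exits ~950 m, 28 days, expected route ~2600 km),
control (2.0 m s⁻¹, ~850 m, 20 days, ~2000 km), delayed (1.5 m s⁻¹,
~650 m, 5 days, ~960 km, tailwind ~3 m s⁻¹, half of low-altitude glides
flapped). The analytic expectation helpers
(`expected_daily_displacement_km`, `expected_migration_distance_km`)
derive the implied route length from the parameters — the recovery tests
compare against these, never against tuned numbers.

What the generator does **not** emulate: terrain (ground elevation is a
constant 0, so above-ground and above-ellipsoid altitudes coincide),
aerodynamic realism (no glide polar, no thermal turbulence), GPS
burst-trigger hysteresis, tag outages, social interaction, and mortality
(survival machinery is exercised with explicit death-date inputs
instead). Passing tests therefore demonstrate that the *computational
rules* recover known structure at realistic noise levels — not that the
flight model is aerodynamically faithful, nor how the pipeline behaves
under terrain-induced altitude error.

## Problem sizes and determinism

The test suite runs the full pipeline on a 3-group × 2-bird cohort
(10/8/5 simulated days; ~360k fixes) and a 30-bird delayed-only cohort
for migration-distance recovery; `scripts/acceptance.py` uses 4 birds per
group at the default day counts (~1.3M fixes, about a minute on one CPU).
These sizes put Monte-Carlo error comfortably inside the stated recovery
tolerances (≥ 30 thermals per group, ≥ 30 birds for distance). Every
random draw flows from a single seed through `numpy` `SeedSequence`
spawning, so identical configurations produce byte-identical CSV outputs;
the CLI serialises the resolved configuration and a row-count manifest
into each output directory.

## Known limitations

- Vincenty's inverse formula can fail to converge for nearly antipodal
  points; irrelevant at migration-track scales but the routine is not a
  general-purpose geodesic library.
- The 60-min main-flight gap rule and the UTC day boundary are declared
  conventions; results for birds that fly around midnight UTC or take
  long midday breaks would shift with these choices.
- `days_in_segment` assumes the entry burst precedes the exit burst of
  the same southward passage; a bird re-entering the segment after
  exiting is not re-counted.
- The exact r×c Fisher enumeration is practical for the 3×2 / small-count
  tables of cohort comparisons; very large or wide tables would need a
  network algorithm or Monte-Carlo p-values, which this package does not
  implement.
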