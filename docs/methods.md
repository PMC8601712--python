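# Methods

This note documents the models and procedures implemented in `njflight`,
the defaults they use, and the choices made where the design was genuinely
open.

## Data model

Loggers report, per bird, an activity score every 5 min (an integer count
of accelerometer sub-measurements registering movement, out of `scale_max`
∈ {10, 5} depending on logger generation), air pressure every 5 min
(sensor accuracy ±1 hPa), and an approximate daily latitude. The on-disk
interchange is one flat CSV row per 5-min timestamp; gaps are absent rows,
never NaN-filled rows. Validation rejects (with the offending row number)
scores outside [0, scale_max], pressures outside (300, 1100) hPa,
off-grid or non-monotone timestamps, and latitudes outside [−90, 90].
A latitude can only be carried on a date that has at least one data row;
this is a limitation of the flat format, not of the in-memory model.

## Barometric altimetry

Pressure is converted to altitude above sea level with the hypsometric
relation for a standard atmosphere with a linear temperature lapse:
h(P) = (T0/L)(1 − (P/P0)^(R0·L/g)), T0 = 288.15 K, L = 0.0065 K m⁻¹,
P0 = 1013.25 hPa, g = 9.8 m s⁻², R0 = 287.058 J kg⁻¹ K⁻¹. The exponent
R0·L/g ≈ 0.19040. The map is strictly decreasing and algebraically
invertible; the simulator uses the exact inverse. Sensor noise of ±1 hPa
corresponds to ~8.3 m of altitude at sea level, growing to ~14 m at
5000 m — the recovery tests assert the brute-force-verified 15-m bound.
Sensor temperature compensation is assumed done on-board. No QFE/QNH or
humidity corrections, and no above-ground-level conversion (that would
require a terrain model).

Two series primitives serve the downstream modules: a centred three-point
rolling mean (endpoints average the two available points so the series
keeps its length), and per-interval vertical displacement Δz with rate
Δz/Δt (Δt = 300 s on a full grid). Near-level classification runs on the
raw series, which defines the change "from the preceding record";
displacement statistics (mean vertical speed, tortuosity, descents, event
legs) run on the smoothed series. Both bases are switchable in
`PipelineConfig`.

## Flight segmentation

A 5-min sample is *flight-level* when score/scale_max ≥ 0.6 — equivalently
score ≥ 6 of 10, generalised to ≥ 3 of 5 for the shorter-sequence loggers
by preserving the duty-cycle fraction (the threshold's original form is
stated only for the 11-grade scale). A UTC clock-hour with ≥ 7 flight-level
samples (of ≤ 12) is a *core hour*; maximal runs of consecutive core hours
form the core period. The episode boundary then moves earlier/later by
5 min per qualifying sample in the single hour adjacent to each end;
qualifying samples need not be contiguous with the core (a contiguous
variant sits behind `pre_post_contiguous`). Episodes strictly longer than
3 h are *migratory*; shorter ones are retained as *short* flights because
terminated exploratory movements are short flights by definition. By
construction two episodes of one bird can touch but never overlap.

Region is assigned from the daily latitude nearest the episode midpoint:
north of 38°N Europe, 8–38°N the Sahara belt (inclusive at both breaks),
south of 8°N sub-Saharan Africa; missing latitude labels the episode
`unknown` and excludes it from regional comparisons only. Season defaults
to the calendar rule (July–December autumn, January–June spring); a
direction rule (net latitude change over the surrounding week, southbound
= autumn) is available and falls back to the calendar when no movement is
resolvable.

## Altitude-variation metrics

Per migratory episode, on the configured bases:

- **Displacement classes.** Each 5-min interval is *level* if |Δz| < 30 m
  (strict: 30 m exactly is intermediate), *intermediate* if 30 ≤ |Δz| <
  300 m, *large* if |Δz| ≥ 300 m (≥ 1 m s⁻¹). The three counts partition
  the intervals exactly; `level_fraction` uses intervals, not samples (an
  off-by-one against tallies counted per record).
- **Mean vertical speed.** The mean of |Δz|/Δt. Unsigned, because a signed
  mean telescopes to near zero on any round trip and the quantity is meant
  to measure vertical motion per unit time.
- **Vertical tortuosity.** Direction shifts divided by (number of
  recordings − 1). Directions follow a zero-carry rule: a zero Δz inherits
  the previous (at the start, the next) non-zero direction, so a staircase
  counts no shifts and plateaus do not split runs. The denominator is
  taken literally, so the attainable maximum is (N−2)/(N−1) < 1; no
  renormalisation.
- **Cruise-phase variants.** The first and last maximal monotone-direction
  runs (the presumed initial ascent and terminal descent) are removed
  before recomputing; profiles that are one or two runs, or whose interior
  has fewer than two samples, are flagged untrimmable.

## Exploratory movements

A *terminated* exploratory movement is a short (≤ 3 h) flight whose
smoothed profile is exactly one ascent run followed by one descent run,
with a climb of ≥ 500 m and a flight-wide mean |Δz|/Δt > 0.1 m s⁻¹. The
500-m requirement binds the ascent; requiring both legs is a config flag
(`terminated_require_both_legs`), and the rate test can be applied per leg
instead (`terminated_rate_scope`). A *mid-flight* exploratory movement is
a pair of adjacent opposite-direction runs inside a migratory episode,
each ≥ 500 m with a per-leg mean rate > 0.1 m s⁻¹; the episode's first and
last runs never participate (they are the ordinary climb-out and final
descent), overlapping candidates resolve greedily left-to-right, and
whether the excursion began with a descent is recorded. Leg rates use the
run's first-to-last non-zero interval, so plateaus absorbed by the
zero-carry rule do not dilute them.

## Ascents and descents

The maximum ascent rate over 5- and 20-min windows is max over all aligned
window positions of (z[i+k] − z[i])/window (k = window/300); a series
shorter than the window, or with no gap-free window, is flagged undefined
rather than zero. For analysis inclusion the flight's total climb (sum of
positive Δz) must exceed the height a bird at the theoretical maximum
climb rate (1.16 m s⁻¹, configurable) would gain in one window; otherwise
small climbs trivially saturate the statistic.

Descent segments are maximal runs of decreasing smoothed altitude, with a
single-interval plateau tolerated inside a run (brief intermittent flight
or an updraft); a strictly-decreasing mode is a flag. A run must follow
flight-level activity, span ≥ 10 min, and contain ≥ 4 records, because the
first and last record (possibly still in powered cruise, or after landing)
are excluded before the rate is computed from the remaining endpoints — a
2-interval descent has no interior pair and therefore no rate. Mode is
*glide* when the mean activity duty over the run is below the 0.6 flapping
threshold, else *active*. Because gliding suppresses the activity that
defines episode boundaries, pipelines search descents on the full per-bird
streams (`find_descent_segments`), not just within episodes. Smoothing
spreads a descent's shoulders by about one sample on each side, which
dilutes recovered rates by roughly one interval per run end — the
recovered glide sink rate on a planted polar descent is accurate to about
0.1 m s⁻¹ for a 45-min glide.

## Flight mechanics

The benchmark power curve is the classical three-term decomposition
P(V) = k(mg)²/(2ρV·Sd) + ½ρV³(Sb·CDb + S·CDpro), with disk area
Sd = πb²/4, allometric body frontal area Sb = 0.00813·m^0.666, air density
ρ = 1.225 kg m⁻³ and body drag coefficient CDb = 0.1. The available-power
ceiling P_max converts the margin into a climb rate,
V_z(V) = (P_max − P(V))/(mg), floored at zero. In the default *calibrated*
mode P_max is solved so that V_z(10 m s⁻¹) = 1.16 m s⁻¹, the published
aerodynamic-model value for this morphology.

The curve's two shape coefficients are themselves calibrated once against
that published model rather than set to generic fixed-wing values: the
induced-power factor (3.63) and profile drag coefficient (0.0112) are the
unique pair for which the minimum-power speed is 7.02 m s⁻¹ (the published
speed of maximum climb) and V_z(8.65) − V_z(10) = 0.13 m s⁻¹ (the
published difference). The third published number, the maximum climb rate
of 1.35 m s⁻¹, is then an untouched validation: the calibrated curve gives
1.346 m s⁻¹. Generic textbook coefficients (k ≈ 1.2, CDpro ≈ 0.02) make
the curve far too steep around its minimum for this wingbeat-averaged
purpose, overestimating V_z(7.02) by ~0.3 m s⁻¹. All coefficients are
overridable.

Gliding is summarised by the best glide ratio (L/D = 11, speed of best
glide 10 m s⁻¹): sink = −V/(L/D), hence the −0.91 m s⁻¹ reference.

**Cost-of-transport scenario.** A flight of fixed horizontal distance
(default 50 km) contains one climb of default 1000 m at the given climb
rate followed by a return to cruise altitude. During climbing (and powered
descent) the bird holds its cruise airspeed, so ground speed is the
horizontal component √(V² − v_vert²) — this is what makes steeper
excursions cost more ground. A gliding descent proceeds at the polar's
best-glide speed at a metabolic cost of a configurable fraction (default
0.4) of level-flight power; a powered descent descends at the climb rate
with the potential energy recovered into thrust at a configurable
efficiency (default 1.0), the required power floored at a configurable
minimum (default 0). The penalty is the total energy over the fixed
distance divided by that of uninterrupted level flight, minus one. With
the defaults the penalty at a 1 m s⁻¹ climb is 8.3% for a gliding descent
and 1.5% for a powered one; the penalty is monotone in the climb rate for
both modes (weakly so for powered descent below the rate at which the
power floor starts to bind). Geometrically infeasible excursions (legs
longer than the available distance) raise an error.

## Group statistics

Responses are compared across season × region cells with a linear mixed
model — cell means as fixed effects, a per-bird random intercept — fitted
by REML (Powell search first; a fit is accepted only with finite, sane
standard errors, otherwise a fixed-effects fall-back is used and logged,
as it also is for single-bird designs). Pairwise contrasts use the
studentized-range (Tukey HSD) adjustment and are displayed as compact
letters computed by insert-and-absorb, so two groups share a letter if and
only if they are not significantly different at α = 0.05. A response with
zero variance yields the degenerate "no differences" comparison rather
than an error. The paired seasonal test is a two-sided paired t on
per-bird spring − autumn values with n − 1 degrees of freedom; a constant
non-zero difference reports an infinite statistic flagged degenerate, not
NaN.

## Synthetic data

The simulator emulates the instrument, not the bird: flights are
piecewise-linear altitude plans (segments of duration, signed
displacement, and flapping duty cycle) built on a 1-s lattice and sampled
at the 5-min grid; pressure is the exact hypsometric inverse of true
altitude plus Gaussian noise (default s.d. 0.5 hPa — the sensor's ±1 hPa
figure is an accuracy bound, not an s.d.); activity scores are binomial
draws of the segment's duty (default 0.95 in flight, 0.02 at rest);
latitude follows a daily trajectory. Days are rest, flights are nocturnal
(a clock rule, not solar geometry); terrain is flat and configurable.
Plans are validated: sustained vertical rates ≤ 2 m s⁻¹, altitude never
below ground, plans return to ground, nights do not overlap. Builders
provide ordinary migratory nights (grid-snapped ascent/wiggly
cruise/descent), terminated and mid-flight exploratory nights, glide
descents, and level-fraction-planted cruises; `migration_scenario`
composes them into a deployment-like mix with both logger scales and
seasonal latitude trajectories. Identical spec + seed reproduces the CSV
byte-for-byte.

What the simulator deliberately lacks — wind, thermals, terrain relief,
sensor drift, irregular duty cycles, real geolocation error — bounds what
passing tests show: they demonstrate that the estimators recover the
quantities the generator defines under instrument-level noise, not that
the biological interpretation of any field dataset is correct.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen to
exercise every code path: scenarios of 1–10 birds and 2–5 nights each,
50 flights for the event-recovery suite, 10³ random series for the
oracle-equivalence checks. All are deterministic under fixed seeds.

## Known limitations

- The flat CSV cannot carry a latitude for a date with no sensor rows.
- An exactly-10-min (2-interval) descent is dropped for lack of an
  interior rate pair; real 10-min descents at 5-min resolution are at the
  detection limit by construction.
- Episode boundaries extend by sample counts, not sample identities, so a
  boundary can cover a non-qualifying sample when qualifying ones are
  scattered through the adjacent hour (matching the counting rule the
  extraction is defined by).
- The mixed model is fitted per response without cross-response
  multiplicity control, mirroring the analysis structure it reimplements.
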