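# Methods

`migtrack` implements a complete GPS-track analysis for a migratory
flight-generalist raptor (the motivating system is the lesser kestrel,
*Falco naumanni*, migrating between Iberia and the Sahel across the
Mediterranean Sea and the Sahara Desert). The pipeline quantifies
migration at three nested scales — trip, day, and hourly segment — and
relates travel behaviour to geography, time of day, and wind. Because
real tracking data are not bundled, a first-class synthetic generator
reproduces the statistical structure the analysis assumes, with exact
ground truth for everything the pipeline estimates.

## Trip detection

The daily-distance series sums consecutive fix-to-fix great-circle
distances per UTC calendar day, assigning midnight-spanning steps to the
day of the arriving fix; calendar days with no arriving step contribute
0 km (gap days within a residence phase are indistinguishable from
stationary days at this scale, and treating them as stationary is the
conservative choice).

Migration onset is the first day of the earliest 3-day window with mean
daily distance ≥ 150 km/day immediately preceded by a stationary phase —
five consecutive days whose mean daily distance is < 70 km/day. The end
is symmetric: the last day of the latest qualifying window immediately
followed by a stationary phase. Two adjacency refinements make the rule
well-posed:

* the window's first (onset) or last (end) day must itself be
  non-stationary (≥ 70 km). Without this, a single 500+ km travel day
  averaged with two residence days still clears 150 km/day, and the
  detected onset slides one or two days into the residence phase. The
  stationary phase must *end* where the migration window begins.
* when several windows qualify, the earliest (onset) and latest (end)
  are taken; onset must precede end, otherwise no trip is reported.

Thresholds (150, 70, 50 km and the 3-/5-day window lengths) are module
constants, overridable through the CLI `--config` file.

## Trip metrics

For a detected trip: duration in days (inclusive); straight-line
(orthodromic) distance from the first fix on the onset day to the last
fix on the end day; cumulative distance as the sum of daily distances;
straightness = straight-line / cumulative ∈ (0, 1]; non-travelling days
are trip days with total daily distance < 50 km; travel speed =
straight-line distance / (duration − non-travelling days). Note the
deliberate asymmetry kept from the field definitions: trip-scale
non-travelling days use *total* daily distance, while daily-scale
travelling days (below) use *directional* displacement.

## Hourly regularisation and travel classification

Tracks are thinned to a nominal 1-h cadence tolerating ±20 min: keep the
first fix, then from each kept fix at time *t* keep the earliest fix in
[*t*+40 min, *t*+80 min]; when the window is empty, jump to the next
recorded fix and continue (a gap). No interpolation is performed; the
output is a subsequence of the input and the operation is idempotent.
Greedy earliest-in-window selection maximises the number of retained
observations. Consecutive kept fixes 40–80 min apart form hourly
segments with great-circle distance, ground speed, and initial bearing;
gap pairs form no segment (bridging a multi-hour gap would fabricate a
slow pseudo-segment). Segments with ground speed ≥ 5 km/h are travel
segments; slower segments are foraging/resting. All segment annotations
(day/night, geography, wind, BLH) are anchored at the start fix — one
convention throughout.

## Solar day/night

Sunrise and sunset come from the NOAA solar-position algorithm with
zenith 90.833° (refraction plus solar half-diameter), evaluated per fix
at the fix's own coordinates and UTC date, with one refinement pass of
the equation of time at the event time. A fix is diurnal iff
sunrise ≤ t < sunset (inclusive start); polar day/night return markers
and classify as diurnal/nocturnal respectively. Civil/nautical twilight
variants and pressure-dependent refraction are out of scope. Day-unit
partitioning is undefined poleward of the polar circles.

## Environmental annotation

Geography is a point-in-polygon lookup against labelled polygons (sea,
desert, non-barrier); boundaries count as inside, the first listed
polygon wins ties, and uncovered points default to non-barrier.
Longitudes are normalised to [−180, 180); the study corridor is far from
the antimeridian, so no wraparound handling is attempted in polygon
tests (documented limitation).

Wind (u, v at a single pressure level) and boundary-layer height are
linearly interpolated — bilinear in lat/lon, linear in time — from a
6-hourly 0.75° grid, implemented as a vectorised weighted sum (xarray's
interpolation serves as an independent cross-check in the tests). The
wind vector is projected on the segment's realised travel bearing θ:

    tailwind  = 3.6 (u sin θ + v cos θ)        [km/h]
    crosswind = 3.6 |u cos θ − v sin θ|        [km/h]

so tailwind² + crosswind² = (3.6 |w|)². Components are converted to km/h
to share units with ground speed; crosswind is kept as an absolute
value. BLH (m) proxies thermal-uplift availability.

## Day units and daily metrics

A migration day runs from one sunrise to the next (capturing complete
day-night cycles for a species that travels at night), each sunrise
evaluated at the bird's position nearest the instant. A segment belongs
to the day containing its start fix. Coverage is the fraction of the 24
clock hours holding at least one segment start (capped at 1; a
sunrise-to-sunrise window can touch 25 clock-hour buckets); days with
coverage < 75% are dropped. A travelling day displaces ≥ 50 km along
the migration axis (the trip's start-to-end bearing), measured as
day-displacement × cos(Δbearing). A day's geography is the class
occupying ≥ 60% of its segment time, else "mixed"; mixed days are
excluded from geography contrasts. Daily metrics: straight-line
distance first-to-last position; travel duration as the summed duration
of travel segments, split into diurnal and nocturnal hours; travel
speed = straight-line / travel duration; nocturnal travel fraction;
daily weather means over travel segments only.

The 24-hour coverage denominator (rather than the actual 23–25 h
sunrise-to-sunrise span) is a deliberate simplification; at the
corridor's east-west extent the difference is minutes.

## Statistics

Continuous responses and predictors are z-scored (sample SD, n−1) so
coefficients are in SD units. Collinearity is screened twice: pairwise
|r| ≥ 0.60 among continuous predictors is an error, and VIF_j =
1/(1−R²_j) ≥ 10 in the full design is an error. Candidate models are
every fixed-effect subset of the full model respecting marginality (an
interaction term requires both main effects), all with a per-individual
random intercept. Gaussian models are fitted by ML (not REML, so AIC is
comparable across fixed-effect structures) via statsmodels MixedLM.
Poisson log-link models (for count-like responses such as daily travel
hours) use an in-house random-intercept likelihood: the per-group
marginal likelihood is integrated over the Gaussian intercept by 25-node
Gauss–Hermite quadrature and maximised with BFGS; it reproduces
lme4::glmer estimates and AIC to within the Laplace-vs-quadrature
difference (tested against R). Among candidates within 2 AIC units of
the best, the most parsimonious (fewest parameters) is selected; ties
break by lower AIC, then lexicographic term order, so selection is
order-invariant.

Schedule contrasts (travel vs non-travel counts across groups) use the
Pearson chi-square without continuity correction — the tables involved
have thousands of counts, where the correction is negligible and the
large-sample (2−1)(k−1) df convention applies. Variance explained is
the Nakagawa–Schielzeth decomposition: R²_marginal = σ²_f/(σ²_f + σ²_r
+ σ²_e) and R²_conditional = (σ²_f + σ²_r)/(σ²_f + σ²_r + σ²_e), with
σ²_f = var(Xβ). For Poisson models the observation-level variance uses
the lognormal approximation ln(1 + 1/λ̄).

## Synthetic data generator

The generator scripts what the pipeline must recover. Each bird holds a
pre-trip residence phase (hourly jitter, a few km/day), migrates between
scripted onset and end dates along a fixed corridor, and holds a
post-trip residence. While migrating, an hourly behaviour state machine
sets airspeed:

| context                    | behaviour            | airspeed (km/h) |
|----------------------------|----------------------|-----------------|
| non-barrier, day           | fly-forage / travel (50:50) | 20 / 30  |
| non-barrier, night         | roost (85%) / sprint (15%)  | 0 / 45   |
| sea, day or night          | continuous flapping  | 42              |
| desert, day                | directed travel      | 30              |
| desert, night              | sprint               | 45              |

Speeds are anchored to the reported behaviour of the species: diurnal
fly-forage below ~25 km/h over land, ~42 km/h continuous flapping over
the sea with no day-night difference, and ~45 km/h nocturnal barrier
sprints. Hourly ground displacement is airspeed +
`tailwind_coupling` × tailwind (sampled from the gridded wind field at
the fix) + Gaussian noise (SD 3 km/h), truncated at zero, stepped along
the local tangent plane toward the destination (curvature error < 0.1%
at ≤ 60 km steps). The destination only fixes the migration axis; trips
are time-scripted and the default destination lies beyond reach so
arrival never truncates a trip. The phase machine keys on the *end*
time of each hourly step, matching the daily-distance convention that
assigns midnight-spanning steps to the arrival day — otherwise the last
pre-midnight sprint of a trip would leak ≥ 70 km into the day after the
scripted end. Scripted mid-trip stopover days (optional) are kept at
least 3 days away from the trip edges so the onset/end windows stay
well-defined.

Geography is a sea band (default 32.0–36.5°N) and a desert band
(19–29°N) spanning the corridor's longitude extent, with non-barrier
elsewhere; southbound birds cross sea first, then desert. Wind is a
configurable mean flow (default v = −2 m/s, i.e. southward support for
the post-breeding direction) plus low-order spatial harmonics whose
coefficients follow an AR(1) process across 6-h steps on a 0.75° grid;
BLH is positive and higher over land by a fixed offset. The default fix
cadence is 60 min with optional independent dropout.

### What the generator does and does not emulate

It reproduces: multi-phase tracks, behaviour- and geography-dependent
speeds, barrier sprints, day/night structure tied to actual solar
events, additive wind support, irregular sampling via dropout, and
scripted stopovers. It does not emulate: orientation error or wind
drift/compensation (displacement is always along the axis), altitude,
energetics, thermalling microstructure, spatially heterogeneous habitat
within classes, or device duty-cycle gap *structure* (dropout is
i.i.d.). Passing recovery tests therefore shows the pipeline is correct
under its stated assumptions, not that real kestrel data meet them.

### Wind-coupling estimation

`estimate_wind_coupling` regresses hourly ground speed on true tailwind
with behaviour-class indicators. The indicators matter: behaviour is
tied to geography and time of day, which in any *single* wind-field
realization correlate with tailwind, so the single-predictor slope is
biased by confounding (measured ≈ 1.14 at 50 birds for a true coupling
of 1.0) while the behaviour-adjusted slope recovers the coupling to
within ±0.01. The same logic applies to real data, where behaviour
would be a latent confounder of any wind-speed regression.

## Problem sizes and tolerances

Test and acceptance runs use 100-bird studies (~60k hourly states,
~19k analysed segments), 500–600 random series for oracle equivalence,
1000 random lat/date pairs for solar checks, and n ≈ 5000–12000
segments for coupling and slope recovery — sizes at which every
stochastic assertion has comfortable margin. Numerical tolerances:
1e-9 for algebraic identities (wind components, chi-square, VIF), 1e-12
for closed forms, 0.01 relative for geodesic-vs-oracle distance, 10 min
for sunrise against the independent NOAA-spreadsheet oracle, and 15 min
for day length against the closed-form hour-angle equation evaluated at
the same 90.833° zenith (comparing against the zenith-90° form would
measure the refraction convention, not the geometry).

## Known limitations

* Calendar-UTC days for trip detection vs sunrise-anchored days for
  daily metrics (both kept deliberately, as the field defines them).
* Whether the original analyses evaluated sunrise at the colony or per
  fix is unknowable from the definitions; per-fix is used.
* Greedy earliest-in-window resampling is one of several defensible
  readings of "1-h interval allowing 20-min deviations".
* The Poisson R² residual variance uses the lognormal approximation,
  adequate for λ̄ ≫ 1 (daily travel hours ~ 10–20).
* No Satterthwaite degrees of freedom or post-hoc Tukey machinery:
  model *selection* and variance decomposition are in scope, per-term
  p-values are not.
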