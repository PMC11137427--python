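# Methods

`telecarbon` estimates the net CO₂ balance of telemedicine in the United
States: the tailpipe emissions a patient avoids by not driving to an
in-person visit, minus the emissions cost of the videoconference's data
transmission, per session and extrapolated to annual national totals.
This note records the model, its assumptions, the tunable parameters, and
the design choices made where the problem was genuinely open.

## The accounting model

For each telemedicine session between one provider and one patient:

1. **Travel distance.** The one-way car-travel distance between the two
   participants' coordinates is obtained from a *router* (any object with a
   `route(origin, destination) -> (miles, hours)` contract whose road miles
   never fall below the great-circle separation). The round trip is exactly
   twice the one-way route — the only reconstruction consistent with a
   one-way distance-matrix query feeding a round-trip figure.
2. **Avoided emissions (savings).**
   `savings_g = round_trip_miles × 404 g CO₂/mile`, the 2022 US EPA average
   passenger-vehicle tailpipe rate (22.0 mpg). Tailpipe only: upstream fuel
   production is excluded.
3. **Videoconferencing emissions (expenditure).**
   `expenditure_g = minutes × 0.036 GB/min × 0.015 kWh/GB ×
   4.33·10⁻⁴ t CO₂/kWh × 10⁶ g/t ≈ minutes × 0.23382 g/min`.
   The 0.036 GB/min rate is for 720p video with two participants, so both
   endpoints' streams are already included; device and data-center embodied
   energy are not modelled.
4. **Net balance.** `net_g = savings_g − expenditure_g`; per-minute net is
   `net_g / duration` (defined as 0 at zero duration, a guard only — the
   filters guarantee ≥ 5 minutes). Net is negative essentially only for
   zero-travel sessions: with default factors savings fall below expenditure
   only when the round trip is under ~0.0006 miles per session minute.

### Car-mode-share adjustment

84.8% of US commuting travel is by car. Scaling distance by 0.848 avoids
crediting non-car travel with tailpipe savings, but the reference analysis
is internally inconsistent about where the factor applies: its per-session
savings column equals 404 g × the *unadjusted* round trip, while its prose
describes adjusting total distance. The package therefore stores the
adjusted distance on every session but exposes the application point as a
switch (`--apply-mode-adjustment {off,per-session,aggregate}`), defaulting
to `off` for per-session figures. In `aggregate` mode the central savings
estimate is scaled by 0.848 before subtracting the central expenditure.

### National extrapolation

No public count of US telemedicine sessions exists. CMS reimbursed
27,691,878 telemedicine sessions in one year and represents 38% of National
Health Expenditures, giving `27,691,878 / 0.38 = 72,873,363` sessions
nationally (expenditure share used as a volume proxy — a strong but stated
assumption). The national total is
`central_net_g × 72,873,363 / 10⁶` metric tons, with the **median** as the
default central estimate (mean available); the headline is rounded to the
nearest 100 tons, with the raw value always emitted alongside.

## Eligibility filter

Retained sessions satisfy all of: exactly 2 participants; duration in
[5, 120] minutes (both endpoints inclusive — the exclusion rule is strictly
"< 5 minutes", and symmetry is applied at 120, consistent with an observed
maximum eligible duration of 119.83); start date within the study window
(2022-01-01 to 2023-02-21, inclusive); one-way geodesic separation
≤ 400 miles (great-circle, not road, distance — distant dyads are assumed
to substitute local care rather than travel); region label present.
Exclusions are attributed to the first failing rule in the fixed order
dyad → duration-low → duration-high → window → geodesic → region, so
reports are deterministic and their counts sum exactly to the input size.

## Stratified proportional sampling

Each eligible session maps to one of 40 strata: region (Northeast,
Southeast, West, Midwest, Southwest) × duration class (short: 5–30 min
inclusive; long: > 30) × day class (weekday/weekend, UTC calendar) × hour
class (peak: 13:00–23:00 UTC inclusive; offpeak otherwise). A duration of
exactly 30 minutes is short, per the class definition "5–30 minutes".
Sample sizes are apportioned by largest remainder (Hamilton): each stratum
gets the floor of its proportional quota, leftovers go by descending
fractional remainder with ties broken by the canonical stratum order. This
bounds every stratum's share distortion below one sampling unit (1/n) and is
fully deterministic. Within strata, simple random sampling without
replacement under a seeded generator. When no sample size is configured,
the pipeline applies the reference sampling fraction 79,904 / 6,231,614
(≈ 1.28%) to the retained population.

## Synthetic data generator

The platform data behind the original analysis is proprietary, so the
generator emulates its published structure; all parameters are one
configuration record (`GeneratorConfig`) and every default below is the
study-population value where one is printed.

- **Regional shares**: Northeast 34.18%, Southeast 20.42%, West 18.99%,
  Midwest 17.26%, Southwest 9.15%.
- **Durations**: bimodal; 44.06% short. Each class is a truncated normal —
  short on [5, 30] (mean 18, SD 7), long on [30, 120] (mean 45, SD 20).
  The source states bimodality but no parametric form; the component
  means/SDs are package choices yielding an overall median near the
  reference 36.7 minutes.
- **Distances**: per-region lognormal one-way geodesic miles, the simplest
  two-parameter right-skewed family. Medians are half the published
  per-region round-trip medians (Northeast 23, Southeast 31.5, West 22,
  Midwest 24, Southwest 24.5 miles); log-SDs are back-solved from the
  published interquartile ratios (1.26–2.05). Because valid sessions are
  capped at 400 geodesic miles, the generator root-solves an effective
  log-location so the median of the *truncated* law equals the configured
  target; the IQR match is a diagnostic, not an enforced invariant.
- **Coordinates**: providers uniform in coarse per-region bounding boxes;
  the patient is placed at the sampled geodesic distance along a uniform
  bearing (exact on the reference sphere). Only pairwise distances feed the
  analysis, so street-level realism is a non-goal.
- **Timestamps**: weekday shares from the published day-of-week counts
  (Mon 17.24%, Tue 22.69%, Wed 22.22%, Thu 21.34%, Fri 13.40%, weekend
  3.10% split evenly); 75% of sessions in the 13:00–23:00 UTC window
  (the peak-window total is not published; 0.75 is a fixed package choice
  reflecting business-hours concentration), uniform within each window.
- **Planted violations**: 2% of records by default, split uniformly among
  too-short, too-long, group-session, > 400-mile, and missing-region
  violations, so the filter stage is genuinely exercised.
- **Seeding**: one master seed; each component (region, duration, distance,
  geometry, time, violations) draws from its own spawned stream in a fixed
  order, so identical configurations give byte-identical tables and adding
  a component cannot perturb existing draws.

**What the generator does not emulate**: population-density-weighted
placement, real road networks, provider specialty mix, serial correlation
within provider accounts, or any IP-geolocation error structure. Passing
tests therefore demonstrate that the *pipeline arithmetic and sampling
machinery* are correct under the published distributional shape — not that
the published sample medians would be recovered from real data.

## Synthetic router

Road distance = geodesic distance × a detour (circuity) factor drawn from
Normal(mean 1.3, SD 0.1) truncated below at 1.0 — typical US road-network
circuity, fully configurable. The draw is a pure function of (seed, origin,
destination) via a splitmix64 hash of the coordinate bits, so repeated
queries agree without stored state. Travel time = road miles / speed
(default 40 mph). The contract (road ≥ geodesic, determinism) is what the
analysis relies on; a live routing client could be dropped in behind it.

## Numerical choices

- Earth modelled as a sphere of radius 3958.8 miles; haversine distances
  are verified against a brute-force great-circle chord-sum integration to
  1e-6 relative.
- Summary statistics: sample SD (n−1; reported 0 for singletons); quartiles
  by linear interpolation between order statistics (the common default in
  mainstream statistical software; the quartile rule affects reported IQR
  endpoints and is therefore documented).
- Largest-remainder ties and sampling order both follow one canonical
  stratum ordering (region, duration, day, hour class indices).
- Generated values are written at fixed precision (durations 0.01 min,
  coordinates 1e-6°), making CSV outputs byte-stable across runs.

## Problem sizes

Distribution-recovery checks run at n = 100,000 generated sessions, where
regional shares land within ±0.5 points and per-region distance medians
within 10% of their targets; end-to-end tests use 3,000–20,000 sessions.
The full pipeline runs at n = 1,000,000 in well under a minute on one CPU
(generation ≈ 11 s).

## Known limitations

- The CMS expenditure share is a payer-mix proxy for session volume; no
  uncertainty is propagated through it.
- Tailpipe-only vehicle emissions and transmission-only videoconference
  energy; clinic building energy and device embodied carbon are out of
  scope.
- The weekend/weekday and peak/offpeak classes use UTC calendar boundaries,
  as the timestamps carry no local timezone.
- One published discussion figure (≈1.46 Mt) is not derivable from any
  combination of the published per-session central estimates and session
  counts; the package reproduces the 1,443,800-ton chain only.
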