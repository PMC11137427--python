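# telecarbon

Carbon accounting for telemedicine. `telecarbon` estimates the net CO₂
balance of replacing in-person health-care visits with video sessions: the
tailpipe emissions a patient avoids by not driving to the provider, minus
the emissions cost of the videoconference's data transmission — per
session, and extrapolated to annual US national totals.

It is aimed at health-services and environmental-health researchers who
need reproducible, configurable emissions estimates from telemedicine
session logs (timestamps, durations, participant coordinates), and ships a
seeded synthetic-data generator so the entire pipeline is testable without
access to proprietary platform data.

## The model

For a session of duration *d* minutes whose participants are separated by a
one-way car-travel distance *m* miles:

- avoided travel: round trip *2m*, savings `S = 2m × 404 g CO₂/mile`
  (2022 US EPA average passenger-vehicle tailpipe rate);
- videoconferencing cost:
  `E = d × 0.036 GB/min × 0.015 kWh/GB × 4.33·10⁻⁴ t CO₂/kWh × 10⁶ g/t`
  (two-participant 720p data volume, fixed-line transmission energy, US
  grid emission rate);
- net per-session saving `N = S − E`, and per minute `N/d`.

A car mode share of 0.848 can be applied per session, at the aggregate
level, or not at all (`--apply-mode-adjustment`). National totals scale a
central per-session estimate (median by default) to the
`27,691,878 / 0.38 = 72,873,363` annual US sessions implied by CMS
reimbursement volume and its share of National Health Expenditures.

The pipeline stages — eligibility filtering (dyads, 5–120 min, ≤ 400
geodesic miles, study window), 40-stratum proportional sampling
(region × duration class × weekday/weekend × peak/offpeak UTC hours, by
largest-remainder apportionment), routing through a pluggable
distance-matrix contract, emissions conversion, extrapolation, and
descriptive reporting — are importable individually or run end-to-end.
See `docs/methods.md` for assumptions and design choices.

## Worked example

Run the full pipeline on a synthetic population of 100,000 sessions:

```sh
telecarbon run --n-sessions 100000 --seed 42 --out-dir out/
```

which prints the run manifest (also written to `out/manifest.json`):

```json
{
  "exclusions": {
    "duration_above_max": 352,
    "duration_below_min": 378,
    "geodesic_too_far": 417,
    "missing_region": 427,
    "not_dyad": 426,
    "outside_window": 0
  },
  "n_input": 100000,
  "n_retained": 98000,
  "n_sampled": 1257,
  "national_estimate": {
    "central_estimate_kind": "median",
    "per_session_net_g": 28797.99,
    "total_savings_metric_tons_rounded": 2098600,
    "total_sessions": 72873363
  },
  "sample_size": 1257
}
```

Reading the numbers: 2,000 of the 100,000 generated sessions violate an
eligibility rule (the generator plants ~2% violations to exercise the
filter) and each is attributed to exactly its first failing rule. From the
98,000 eligible sessions a proportional sample of 1,257 (the reference
study's ≈1.28% sampling fraction) is drawn across the 40 strata. The
sampled median net saving is ≈28.8 kg CO₂ per session — the synthetic
population's detour factor and distance spread make this a plausible-order
figure, not a reproduction of any published sample statistic — and scaling
it to 72,873,363 annual US sessions gives ≈2.10 million metric tons per
year. Per-session results, stratum allocation, and mean/SD/median/IQR
summary tables by day of week, region, and session length land beside the
manifest in `out/`.

Library use mirrors the CLI:

```python
from telecarbon import EmissionFactors, session_expenditure_g, travel_savings_g

factors = EmissionFactors()
travel_savings_g(49.05, factors)        # 19816.2 g CO2 for a 49.05-mile round trip
session_expenditure_g(36.73, factors)   # 8.59 g CO2 for a 36.73-minute call
```

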