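# nesttrack

Satellite-telemetry analysis for nesting sea turtles, built around the
workflow used to study leatherback females tagged on a small island rookery:
Argos track filtering and state-space regularization, migration-onset
segmentation, nesting-event detection from tag wet/dry sensors, home-range
estimation, marine protected-area (MPA) coverage scenarios, EEZ residency,
and fishing-effort overlap. A ground-truthed synthetic-data generator makes
the whole pipeline testable end to end without any external downloads.

It is written for movement ecologists and conservation analysts who receive
(i) Argos-style location tables, (ii) hourly percent-dry timelines from the
same tags, (iii) region polygons (coastline, reserve, EEZs) and (iv) gridded
fishing-effort tables, and need per-animal breeding and migration summaries
plus spatial-protection metrics.

## Methods at a glance

- **Filtering.** Drop Argos location classes 0 and Z (unquantified error),
  positions on land during the inter-nesting period, and fixes implying
  speeds > 15 m/s (deterministic forward sweep; haversine distances on a
  sphere of radius 6371 km).
- **Regularization.** A continuous-time correlated-velocity process per
  coordinate — position integrating an Ornstein-Uhlenbeck velocity,
  dv = −β v dt + σ dW — fitted per animal by maximizing the Kalman-filter
  likelihood with measurement error fixed per Argos class, then RTS-smoothed
  onto an exact grid (4 h for breeding-season analyses, 1 day for the
  migration/effort overlay), with a per-point sd from the smoother.
- **Migration onset.** Displacement from the tagging site d(t) is segmented
  by Lavielle's penalized contrast: dynamic programming minimizes
  J(K) = Σ_s n_s log σ̂²_s over segmentations with a minimum segment length
  of 12 h and up to 6 segments; K is picked by the normalized second-
  difference threshold rule. The first breakpoint marks the migration, and a
  short local refinement walks to the start of the sustained displacement
  rise (the actual departure).
- **Nesting events.** Hours with > 60 % dry time (≥ 36 dry minutes — the
  worst-case hourly share of a ≥ 72-min emergence split across two hours)
  form candidate events, confirmed against the *unfiltered* fixes within
  ±1 h, and classified: events within 10 d of a later event, and isolated
  single-hour spikes flanked by recorded 0 % hours, are failed attempts.
- **Space use.** IID / OU / OUF movement models (optionally with one
  sine/cosine harmonic at the ~11.5-d inter-nesting period), exact Gaussian
  likelihoods via Kalman filtering, lowest AIC wins (parsimony on ΔAIC < 4
  ties). The utilization distribution is a kernel density with bandwidth
  H = Σ̂ · N_eff^(−1/3), where N_eff = duration/τ_p captures
  autocorrelation; the 50 % and 95 % highest-density contours are the core
  area and home range.
- **Protection and threat.** Time-in-polygon from regular-grid point counts;
  reserve-expansion scenarios as coastline buffers (2–10, 15, 20 km) clipped
  to the reserve's alongshore extent; union and intersection of individual
  core areas; EEZ residency by point-in-polygon; 0.1°→0.5° fishing-effort
  aggregation, Feb–Aug yearly sums, long-term per-cell means, and an
  explicit track-exposure index (Σ of visited cells' mean effort hours).

## Worked example

Simulate a small cohort and run the full pipeline:

```bash
nesttrack simulate --out sim --seed 5
nesttrack run --argos sim/argos.csv --drytime sim/drytime.csv \
    --regions sim/regions.geojson --effort sim/effort.csv --out results
```

or, equivalently, in Python:

```python
from nesttrack import synthetic as syn, pipeline

cfg = syn.SimConfig(seed=5, n_animals=3)
regions, truths, argos, dry = syn.simulate_cohort(cfg)
effort = syn.simulate_effort(regions, cfg, seed=5)
report, summary, artifacts = pipeline.run_cohort(argos, dry, regions,
                                                 effort=effort)
print(report.to_string(index=False))
```

which prints (abridged) the per-animal report:

```
animal_id   tag_date migration_start  observed_nesting_duration_days  estimated_nesting_attempts  successful_clutches  migration_group  final_displacement_km  deployment_duration_days
turtle_01 15/01/2019      16/03/2019                              60                           6                    5 central_atlantic                   2033                       135
turtle_02 15/01/2019      15/01/2019                               0                           1                    1 central_atlantic                   2529                        86
turtle_03 14/01/2019      28/02/2019                              45                           5                    4 central_atlantic                   1919                       117
```

`turtle_02` is an immediate migrant: a single emergence on the tagging
night and a nesting duration of 0 days. The cohort summary reports the
mean ± sample sd of each column; with this seed the pooled inter-nesting
interval estimate is 11.63 ± 1.13 days against the generator's 11.5-day
clock. `artifacts` carries the stage outputs: per-animal utilization
contours, reserve/buffer coverage tables, EEZ residency percentages (the
inter-nesting phase stays entirely in the local EEZ) and per-gear effort
exposure for the migration legs.

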