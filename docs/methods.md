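# Methods

This note records the models, parameter choices and numerical decisions
behind `nesttrack`, in the order the pipeline runs them, together with what
the synthetic-data generator does and does not emulate.

## Track filtering

Argos fixes carry a quality class (3, 2, 1, 0, A, B, Z; ~0.4 km error for
class 3, > 10 km for the worst classes). Three filters are applied, in
order:

1. **Class filter** — classes 0 and Z dropped by default. Classes A and B
   are *retained* even though B's error exceeds 10 km; this mirrors common
   field practice but users should be aware the regularizer then relies on
   the per-class error model to downweight them.
2. **Land filter** — positions strictly inside the land polygon are removed
   during the inter-nesting window only. Because the migration onset is
   unknown before segmentation, the filter runs twice: over the full track
   before the first regularization/segmentation pass, then re-scoped to
   [tagging, onset) for the final tracks. Boundary points are kept (strict
   interior test).
3. **Speed filter** — a forward sweep keeps a fix only if the great-circle
   speed from the last kept fix is ≤ 15 m/s; the downstream member of each
   violating pair is dropped. One pass reaches the fixpoint, making the
   filter deterministic and idempotent. If the *first* fix is the outlier
   the sweep anchors on it; with Argos data this is rare and the class
   filter usually removes such fixes first.

All distances are haversine on a sphere of radius 6371 km.

## Regularization: correlated-velocity Kalman smoother

The reference workflow regularized tracks with a Bayesian hierarchical
first-difference correlated random walk fitted by MCMC. Here that role is
played by a deterministic maximum-likelihood analogue, fitted per animal
(no hierarchical pooling): per coordinate, position integrates an
Ornstein-Uhlenbeck velocity,

    dx = v dt,    dv = −β v dt + σ dW,

discretized exactly between observation times. The reversion rate β and
process scale σ² are estimated by Nelder-Mead on the Kalman-filter
likelihood (log-parameters, bounds log β ∈ [−9.5, 2.5] h⁻¹); measurement
sd is fixed per Argos class (defaults 0.4 / 1.0 / 1.5 / 4.0 / 10 / 10 / 14
km for 3 / 2 / 1 / A / B / 0 / Z — only the endpoints are pinned by the
Argos literature, the middle values interpolate standard figures and are
configurable). The RTS smoother is then evaluated on the union of
observation times and an exact output grid (first fix + k·Δ; Δ = 4 h for
breeding-season analyses, 1 day for the migration overlay), reporting a
per-point position sd from the smoother covariance. Numerical choices: the
state starts at the first fix with position variance 10⁴ km² and stationary
velocity variance σ²/(2β); covariances are symmetrized each step; if the
optimizer fails to produce a finite optimum the smoother falls back to a
random-walk position model with a warning. In the noise-free
constant-velocity limit the smoothed grid reproduces exact linear
interpolation to < 10⁻⁶ degrees, and the smoothed states equal the dense
generalized-least-squares solution of the equivalent joint Gaussian system
(tested to 10⁻⁸).

Tracks are smoothed in a local equirectangular tangent plane about the
track's mean position. For migration tracks spanning thousands of km this
distorts the assumed error isotropy by a few percent at the extremes; the
forward/inverse mapping is self-consistent, so positions are unaffected —
only the relative weighting of very distant fixes is approximate.

## Migration onset

The displacement series d(t) (great-circle km from the tagging site; the
squared series is available by configuration but the plain distance is
what the analysis segments) is partitioned by Lavielle's penalized
contrast. Dynamic programming computes, for each k ≤ Kmax, the exact
minimum of J(k) = Σ_s n_s log(max(σ̂²_s, 10⁻¹²)) over segmentations with
segments of at least Lmin points (defaults: Lmin = 3 points = 12 h at the
4-h grid, Kmax = 6; the variance floor handles constant segments). K is
chosen by Lavielle's threshold rule: the contrast decrease is normalized so
the average per-step drop is 1 (scale Kmax−1), and the largest interior k
whose second difference exceeds 0.75 wins, else K = 1. A [0, 1]
normalization without that scale makes the rule inert (all second
differences fall below any useful threshold), so the scaled form — the one
the field's standard implementation uses — is adopted.

The first breakpoint lies on the outbound displacement ramp but not
necessarily at its base: the early ramp is statistically indistinguishable
from inter-nesting excursions (up to ~108 km) until displacement leaves
that range. The onset is therefore refined deterministically: walk back
down the monotone rise to the ramp bottom, estimate the migratory rate as
the median per-step increment just above it, then walk forward to the
first step at ≥ half that rate. Sub-rate steps at the bottom are the
smoother rounding the corner over the (land-filtered, hence unobserved)
final beach visit. On zero-error, densely sampled synthetic tracks this
recovers the simulated departure within one 4-h grid step; with default
Argos noise the error is a few hours. K = 1 ⇒ the animal never migrated
(tag died early); a breakpoint whose after-mean does not exceed its
before-mean is flagged `unconfirmed`.

## Nesting detection and classification

Hourly percent-dry values strictly above 60 % form maximal runs; each run
is one candidate event timed at the run midpoint. The threshold encodes a
worst-case ≥ 72-min emergence split evenly across two clock hours: 36 dry
minutes, i.e. 60 % of an hour. Runs longer than 3 h are flagged anomalous
(an emergence lasts ≤ 187 min) but still processed. A candidate is
confirmed on land if any fix of the *unfiltered* Argos table within ±1 h
lies on land or within 2 km of the beach — quality class is deliberately
ignored here; unconfirmed candidates are retained and flagged.

Classification applies two failure rules: (1) a single-hour peak whose
neighbours are both *recorded* as exactly 0 % dry is a failed attempt (a
missing hour record leaves the rule inapplicable — absence of data is not
a zero); (2) among the remaining events, a forward sweep fails the earlier
member of any pair closer than the 10-d re-nesting window, so a chain at
days 0, 5, 12 resolves to failed, failed, successful. Every event ends
with exactly one status.

Two interval summaries are reported. `successful_intervals` are the gaps
between classified-successful events — the quantity the 10-d rule acts on,
and therefore right-censored below 10 d by construction. The cohort-level
**inter-nesting interval estimate** instead pools gaps between consecutive
*detected* emergences of any status: every emergence marks a beach return
on the same physiological clock, and this estimator is unbiased for the
return interval (the successful-only version is pushed upward whenever a
true gap falls below the window and the earlier event is demoted, merging
two gaps into one). Candidate-count monotonicity in the threshold holds
for the unimodal peak runs real emergences produce (an event's central
hour is its maximum); it is not a property of arbitrary series, where a
raised threshold can split one run into two.

Durations in reports are whole calendar-day differences (end date minus
start date), and dates render as DD/MM/YYYY.

## Space use

Inter-nesting tracks (the regular 4-h grid truncated at the onset; at
least 20 points) are fitted with six stationary Gaussian models: IID, OU
(position autocorrelation time τ_p) and OUF (adds velocity time τ_v <
τ_p), each with a constant mean or with one added sine/cosine harmonic at
the inter-nesting period (default 11.5 d, overridable per animal; no
automatic tuning). Likelihoods run through the exact state-space forms
(the OUF process is the two-pole CARMA form; transitions and process
noise come from the Van Loan augmented exponential, the stationary
covariance from a Lyapunov solve), with the regularized track's per-point
sd as measurement error. Mean coefficients are profiled by filtering the
regression basis alongside the data and solving the whitened least-squares
problem — exact GLS through the filter. Parameters are counted as 2
variance + 0/1/2 correlation + 2 × mean-basis size; lowest AIC wins and
ties within ΔAIC < 4 go to the fewest parameters, replacing visual
variogram inspection with an explicit parsimony rule.

The utilization distribution is a Gaussian kernel density over the track
in a local Lambert azimuthal equal-area projection, bandwidth
H = Σ̂ · N_eff^(−1/3) with N_eff = min(n, duration/τ_p) for OU/OUF and
N_eff = n for IID — a reference-bandwidth stand-in for full area-corrected
autocorrelated KDE that preserves the outputs the analysis needs (50 %/95 %
contours with areas). Cell masses are normalized to sum to one; the
highest-density threshold for each level comes from the sorted cumulative
mass; contour polygons are traced by marching squares on a zero-padded
grid (holes inside a contour are not carved out — irrelevant for the
unimodal densities seen here); areas are counted from cells at or above
threshold, which makes 50 %/95 % area monotonicity exact. Default grid
resolution 1 km; a built-in refinement check warns when halving the
resolution moves the largest contour area by more than 5 %. Against the
closed-form 50 % highest-density area of a bivariate normal,
2π ln 2 |Σ|^{1/2}, the estimate lands within ~7 % at n = 4000 (the
reference bandwidth inflates the density's covariance by n^(−1/3)).

## Coverage, residency, fisheries

Time in a polygon is the percent of regular-grid points strictly inside
it. Buffer scenarios take the coastline segment adjacent to the reserve,
buffer it seaward by each distance (land subtracted), and clip laterally
with a fan of rays from the island centroid through the segment's
alongshore extent — on the synthetic island the 2-km buffer reproduces the
reserve's marine part to a Hausdorff distance under 0.1 km. Nested buffers
are exact up to arc-discretization slivers (≪ 0.1 % of area). Core-area
union and intersection are n-ary shapely operations; all areas are km² in
a local equal-area projection. EEZ residency assigns each point to the
first-declared region covering it (boundary ties included), with the high
seas as the remainder, so percentages partition to 100 exactly.

Fishing effort is summed from 0.1° to 0.5° cells (lower-left-origin,
half-open; totals conserved exactly), restricted to February–August,
summed within years and averaged over years (cells absent in a year count
as zero), with a combined gear appended. The exposure index — Σ over daily
positions of the visited 0.5° cell's long-term mean hours, and its per-day
mean — is this package's own explicit statistic; the original comparison
of tracks with effort maps was visual, and no numeric overlap measure
exists to reproduce.

## Synthetic data: what it emulates, and what it does not

Each simulated female is tagged on the nesting beach at the end of a
clutch; subsequent beach returns follow a Normal(11.5, 1.8)-day clock
truncated at ≥ 8 d until 1–4 successful clutches are laid, each return
failing with probability 0.3 (the failed fraction is not a published
quantity; it is a configurable default). Successful emergences last
Uniform(72, 187) min; failed ones are shorter and come in the two
signatures the classifier targets — a single-hour dry spike (80 % of
failures; 40–58 min aligned within one clock hour) or an hour-straddling
short emergence (62–71 min). Between returns the turtle loops offshore
(biased out-and-back excursions up to 108 km with a Brownian-bridge
wiggle); after the final clutch she departs at a fixed group heading —
central-Atlantic residents run ~40–60 d of directed movement at 45 km/d,
South-America migrants ~80–110 d — followed by 30 d of area-restricted
search at 15 km/d. Argos fixes arrive as a Poisson process (8/day) with
per-class isotropic Gaussian error; hourly dry time is the exact on-land
overlap plus a ≤ 20 % surfacing background that is exactly zero in about
half the hours (so the flanking-zero rule has realistic traction).
Inter-nesting movement is simulated in a tangent plane (< 0.5 % error
within 500 km); the migration leg uses spherical dead-reckoning. All
outputs are reproducible from (seed, animal index).

Not emulated: currents and bathymetry, diving behaviour, Argos error
tails (errors are Gaussian, real class-B errors are heavy-tailed), duty
cycling and transmission gaps, and nest-site relocation between beaches.
Passing tests therefore demonstrate the pipeline's correctness under the
stated statistical structure, not robustness to every artefact of real
Argos data.

## Problem sizes in the test-suite

Tests run the full pipeline on cohorts of 1–3 animals with shortened
migrations, parameter-recovery checks at n = 200–500 grid points, the
segmentation oracle at n = 30 against exhaustive enumeration (20 random
series), the smoother oracle at n = 12 against a dense GLS solve, the KDE
area oracle at n = 4000, and AIC family recovery over 8 seeded replicates
at n = 300. The interval-recovery check uses the full default cohort of
10 animals. These sizes were chosen to exercise every code path at desk
scale while keeping the statistical checks well-powered.

## Known limitations

- No hierarchical pooling across animals in the smoother, and no
  behavioural-state switching (deliberately out of scope).
- The reference-bandwidth UD slightly over-smooths relative to
  area-corrected autocorrelated KDE; contour areas carry an upward bias of
  order N_eff^(−1/3).
- The buffer construction assumes a roughly convex coastline around the
  reserve (the ray-fan clip); deeply concave coasts would need a proper
  alongshore corridor.
- The speed filter's forward sweep anchors on the first retained fix.
- Group classification uses a fixed 3,200-km displacement threshold (the
  midpoint of the observed gap between dispersal groups) with a 30-d
  minimum track length; both are configurable.
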