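# Methods

## The model

A trained homing pigeon released repeatedly from the same site tends to fly
an idiosyncratic *habitual route* home.  `routegp` treats each recorded
flight as an imperfect, noisy attempt to reproduce that route, which is
itself never observed.

Write `s(t)` for the straight release-to-loft *beeline*, parametrized by
normalized flight time `t ∈ [0, 1]` (0 = release, 1 = arrival).  The model
has three layers, each a Gaussian process with a stationary Matérn kernel
`k(t, t') = λ² g_ν(√(2ν) |t−t'| / σ)`:

1. **Habitual route** `h(t) ~ GP(s(t), k_θ)` with route scales
   `θ = {λ_h, σ_h}`.  By symmetry — absent any knowledge of the landscape —
   the route prior is centred on the beeline.
2. **Flights** `x_i(t) | h ~ GP(h(t), k_φ)`, i.i.d. across flights, with
   flight scales `φ = {λ, σ}`.  Flight-to-flight variation is uncorrelated
   between flights; only the route is shared.
3. **GPS noise**: isotropic `N(0, η²)` per observation; typical logger
   accuracy anchors the prior for η at 5 m.

The two planar coordinates (metres east/north of a local origin) are
modelled as independent GPs sharing one hyperparameter set, so
log-likelihoods add over dimensions.  Marginalizing `h` analytically gives
a joint Gaussian over all flights with covariance

    Σ = blockdiag_i[k_φ(t_i, t_i)] + k_θ(t_all, t_all) + η² I,

i.e. within-flight blocks `k_φ + k_θ + η² I` and cross-flight blocks `k_θ`.
Prediction of an unseen flight and the posterior mean of the route are the
standard Gaussian conditionals of this joint.

The Matérn order ν is configurable in {1/2, 3/2, 5/2} with a smooth 3/2
default; results are insensitive to the exact member of the family, which
is why the class is exposed rather than a single hard-coded form.

### Exchangeable fast paths

All flights are resampled onto one common `t`-grid (default 100 points), so
Σ has the exchangeable form `I ⊗ (k_φ + η²I) + J ⊗ k_θ`.  An orthogonal
contrast transform across the flight index block-diagonalizes it into one
`(k_φ + η²I + n k_θ)` block plus `n−1` copies of `(k_φ + η²I)`, reducing an
`(ng)³` factorization to two `g³` ones.  The same identity collapses the
leave-one-out conditionals used in waypoint selection to one `m×m` solve
plus one grid-sized factorization shared by every flight.  Dense assembly
is retained for ragged time grids and serves as the independent oracle in
the test suite.

## Hyperparameter treatment

The five hyperparameters `(λ, σ, λ_h, σ_h, η)` get independent log-normal
priors.  Two anchorings are provided:

* `HyperPrior.default(beeline_length)` — output scales at 10% of the
  beeline length (log-std 1.0), input scales at 0.1 of the flight duration
  (log-std 1.0), η at 5 m (log-std 0.5).  Used wherever the likelihood is
  allowed to correct the scales, i.e. posterior (MCMC) inference.
* `HyperPrior.from_flights(flights)` — output-scale medians at the pooled
  RMS deviation of the flights around the beeline (split evenly between the
  flight and route components; log-std 0.5).  **Used for waypoint
  selection**, which by design marginalizes hyperparameters under the prior
  without likelihood correction: with geometry-anchored scales, essentially
  every prior draw predicts deviations far larger than near-beeline data
  exhibit, and any single waypoint then earns a large spurious information
  gain simply by resolving that phantom route uncertainty (log Bayes
  factors of +10 to +18 on ensembles with *no* shared route).  Anchoring at
  the data's own deviation scale keeps the Occam penalty meaningful while
  remaining weakly informative.

Posterior sampling is Gaussian random-walk Metropolis–Hastings in
log-hyperparameter space (where the priors are normal).  During burn-in the
proposal adapts twice over: a scalar step tuned toward 25% acceptance, and
the proposal covariance re-estimated from the chain history (Haario-style)
so the walk aligns with the weakly identified `(λ_h, σ_h, η)` ridge; both
adaptations freeze when burn-in ends, so the retained chain satisfies
detailed balance.  Defaults are 1000 retained samples after 500 burn-in
iterations; the calibration experiments below use 1500/1500 because the
ridge mixes slowly.  Marginal probabilities are log-mean-exp averages over
the sampled hyperparameters.

## Predictability: marginal information gain

The MIG of flight *i* is

    MIG_i = log p(x_i | x_{i−1}, x_{i−2}, M) − log p(x_i | M),

in nats, with both terms hyperparameter-marginalized over the posterior fit
to the two conditioning flights (the smallest honest information set; with
fewer than two predecessors, whatever exists is used and the count is
flagged).  Positive MIG ⇒ the flight is more probable in the light of its
predecessors — route-following behaviour; negative MIG ⇒ the flights are
more probable as independent draws.  MIG is reported as a whole-trajectory
total; a per-grid-point variant is available.  The learning curve
aggregates per-flight MIG across birds as a median with interquartile
range.

## Waypoint identification

A waypoint is a time `t` (and the corresponding point on the posterior-mean
route) whose observations across flights are maximally informative about
the remaining flights.  The objective for a candidate set `t^m` is the
summed leave-one-out MIG; selection is greedy forward over the N = 100 grid
candidates, and after each tentative pick a Bayes factor compares the model
with the already-selected waypoints (M0) against the model with one
additional waypoint whose position is marginalized uniformly over all N
candidates (M1):

    log BF = log[(1/N) Σ_j exp(Δ_j)],

where `Δ_j` is candidate *j*'s objective gain.  Selection stops at the
first `log BF < 0`.  The uniform-position marginalization is the Occam
penalty: a waypoint is accepted only when gains are large over enough of
the grid to outweigh the many candidates that add nothing.  Ties at the
argmax break toward the earliest time; waypoint locations are the
importance-weighted (by joint likelihood) posterior-mean habitual route at
the selected times.

### How many waypoints the algorithm selects — and why

A point worth understanding before interpreting outputs: with a stationary
route kernel, the accepted-waypoint count tracks the number of route
*correlation lengths* across the deviating part of the flight, not the
number of discrete "turns" a human would draw.  Fitting a localized detour
of amplitude A forces `λ_h ≈ A` globally, so each additional waypoint earns
a genuine gain of roughly `0.5·log(1 + λ_h²/λ²)` per resolved correlation
length until the whole deviating span is covered.  On synthetic routes
with three localized detours the algorithm therefore finds the three
apexes first (almost always within 0.05 of the truth) and then continues
to accept a handful of further points along the deviating span, stopping
at ~4–9 total when detour amplitude is ~2× the flight-level variation, and
later still for larger amplitude ratios.  On ensembles with *no* shared
route it selects 0–1 waypoints.  This mirrors the behaviour reported for
real training data (typical counts around 7–10 from five flights), and it
is why the simulator's turn-recovery experiments measure both the apex
localization of the first picks and the total count separately.

## The synthetic-data generator

`SimConfig`/`sample_flights` emulate a training study: a ~5 km beeline,
20 releases (tests use fewer), a 100-point common grid, flight-level
variation λ = 150 m with input scale 0.25, route scale λ_h = 500 m with
input scale 0.2, and η = 5 m GPS noise, exported at 1 Hz as CSV or GPX so
the full ingestion pipeline can be exercised end-to-end.  Route modes:

* `gp_draw` — the model's own generative assumption (one shared GP route);
  used for calibration and MIG experiments.
* `piecewise` — beeline plus localized smooth (Gaussian-profile) detours
  peaking exactly at given turn times (half-width 0.1 by default),
  detrended to pass exactly through release and loft.  This provides
  unambiguous ground-truth turns for recovery experiments.  Sharp-cornered
  (triangular) detours were deliberately avoided: their edge kinks are
  genuine structure that the selector correctly flags, contaminating the
  ground truth.
* `beeline` — no shared route at all; the Occam null.
* `independent_routes` — a fresh route per flight; the "no habitual route"
  null for MIG sign experiments.

What the simulator does **not** emulate: wind and weather, road- or
edge-following dynamics, time-warping between flights (a bird pausing or
circling stretches its time axis in a way the model cannot remove — the
stationary-section filter in the ingestion pipeline mitigates but does not
eliminate this), flock effects, and non-Gaussian outliers.  Passing tests
on synthetic data therefore demonstrate internal consistency of model,
inference and selection — not that real flights satisfy the model.

## Numerical choices

* Cholesky everywhere; no explicit inverses.  Relative jitter escalates
  from 1e-10·mean(diag) tenfold up to 1e-4·mean(diag), then a numerical
  error naming the condition estimate is raised.
* Time normalization uses the post-cleaning first/last samples; the
  stationary filter seeds on windowed displacement speed (< 1 m/s over 5 s
  by default — pigeons cruise at 15–20 m/s) and grows flagged runs while
  instantaneous step speed stays below threshold, so whole stops are
  removed, never the track endpoints.
* The local equirectangular projection (R = 6 371 000 m) is exact enough
  over < 20 km that its distortion is far below GPS noise; its closed-form
  inverse makes round-trips testable to 1e-9°.
* Problem sizes in the test-suite experiments (grids of 40–100 points,
  3–10 flights, MH chains of 150–1500 samples, 20-seed replications) were
  chosen as the smallest sizes at which the statistical assertions are
  stable under the fixed seeds; the library defaults remain the study-scale
  values given above.

## Known limitations

* Waypoint counts on strongly structured routes exceed the number of
  human-labelled turns for the structural reason described above; treat
  counts as "informative regions per correlation length", not "number of
  landmarks".
* λ_h and σ_h are weakly identified from a single realized route; their
  posteriors remain prior-dominated and mix slowly (hence the adaptive
  proposal and long chains in calibration work).
* The flight-level / noise split (λ vs η) degrades when σ is small enough
  that flight wiggles look like noise at the grid resolution.
* No time-warping alignment between flights; no cross-dimensional
  covariance (isotropy is assumed throughout).
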