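# Methods

## Information decomposition on abundance series

Each species is an agent X with a 1-based abundance series x_1 … x_T.
All measures concern the transition to x_{n+1}: the destination history is
x_n^(k) = (x_n, …, x_{n−k+1}); the sources' histories (every other
species, concatenated in input order) are sampled at time n + 1 − d with
length l per source.  The default analysis uses k ∈ {10, 15, 20},
l = k − 1 and d = 2.  The delay reflects the mechanism of abundance-
mediated interaction: a change in one species' abundance can alter
another's metabolic environment at the next step at the earliest, and its
abundance one step after that.  With l = k − 1 the destination and source
validity ranges coincide, so the first well-defined local value of every
measure sits at step k + 1.

Local measures, all in nats:

* entropy h = −log p(x_{n+1});
* active information storage a = log p(x_{n+1} | x_n^(k)) − log p(x_{n+1});
* apparent transfer entropy from source Y:
  t_{Y→X} = log p(x_{n+1} | x_n^(k), y_{n+1−d}^(l)) − log p(x_{n+1} | x_n^(k));
* collective transfer entropy t: as above with the concatenated vector of
  all sources (a sum of incrementally conditioned TEs, not of apparent
  TEs);
* intrinsic uncertainty u = −log p(x_{n+1} | x_n^(k), v_{n+1−d}^(l)).

These satisfy h = a + t + u identically; the estimators below preserve
that identity exactly under plug-in counting and to a small residual
(≈0.003–0.01 nats on Gaussian benchmarks) under k-NN estimation.

Local signals are estimated from the whole series even though the series
are not stationary.  That is a deliberate convention: it maximises sample
size at T ≲ 200, but it means editing the series anywhere can move local
values elsewhere.  The effect-classification stage exists partly to flag
the resulting artefacts.

## KSG estimation

All densities are estimated with the Kraskov–Stögbauer–Grassberger
construction (algorithm 1) and its Frenzel–Pompe conditional extension:
for each point, the Chebyshev distance to its knn_k-th neighbour in the
full joint space sets a radius; counts of points strictly inside that
radius in the marginal subspaces enter digamma terms.  Entropies use the
same radii via Kozachenko–Leonenko (h = ψ(N) − ψ(knn_k) + D·log 2ε, and
the conditional variant with the marginal count replacing N).  Defaults:
knn_k = 4 (standard practice; the variance/bias trade-off is flat around
it at these sample sizes) and max-norm throughout.

Coordinates are standardised per column before the search.  Uniform noise
on [0, noise_amplitude · sd] (default amplitude 1e-8; unit scale when a
column is constant) is added to every coordinate.  This is mandatory, not
cosmetic: abundance data contains long runs of identical values, and with
more than knn_k exact ties the neighbour radius degenerates to zero — if
noise is forced off, a TieDegeneracyError is raised rather than returning
garbage.  Because the noise perturbs tie-breaking, every estimate is
averaged over n_estimation_runs independent noise draws (default 25).
Twin scenarios (disturbed vs undisturbed, manipulated vs plain) are
estimated with *paired* noise streams so identical inputs give identical
signals.

Significance uses a one-sided permutation test: the source block's rows
are permuted (destination blocks fixed), the average measure recomputed
per surrogate, and p = (1 + #{surrogate ≥ observed}) / (1 + n_surrogates)
with n_surrogates = 100 by default.  The flag applies per signal;
reporting zeroes the values of non-significant signals but keeps the flag
so unfiltered values can be regenerated.

Two estimator behaviours worth knowing on near-discrete data:

* KSG mutual information with tiny noise agrees closely with the discrete
  plug-in value on stochastic chains (observed |Δ| < 0.01 nats), which is
  what lets exhaustive-counting oracles validate every measure.
* h and u are *differential* entropies of the noise-smeared data.  On
  heavily tied (near-discrete) coordinates they are large and negative
  (−log of a huge density); the decomposition still balances because the
  scale terms cancel between h and u.  Non-negativity of u is therefore a
  property of the plug-in/discrete view, and of continuous data with
  O(1) noise scales — not of the differential estimate on plateau data.
* on exactly constant plateaus the collective TE is correctly near zero
  (a constant next value is already fully predicted by the own past), so
  plateau CTE levels here are small; agent-based data whose "constant"
  phases micro-fluctuate can show much larger plateau CTE, an effect of
  high-dimensional small-sample estimation rather than of transfer.

## The synthetic community

The simulator is a deliberately small discrete-time resource–consumer
model standing in for an agent-based metabolic community simulation, with
seven species named after the SIHUMI (simplified human intestinal
microbiota) genera.  Mechanism per step: each individual demands a
per-capita uptake from a shared pool; species are served in order of
increasing uptake and are either fully fed or scavenge the remainder
(emptying the pool); fully fed species below the carrying capacity grow
by Binomial(N, growth_rate); underfed species hold constant until they
have starved for more than starvation_tolerance consecutive steps, then
decay by max(1, Binomial(N, death_rate)); zero is absorbing; feedings
(after steps 35, 62, 121 in the 184-step base scenario) add
resource_refill to the pool.  Binomial growth/decay is the only source of
randomness, so plateaus are exactly constant and a fixed seed is
bit-reproducible.

Defaults (initial abundance 10 per species, capacity 500, refill 14000,
and the per-species rate tables in `CommunityConfig`) were chosen once to
produce the qualitative phase structure the analysis needs: initial
growth in all species, ≥10-step plateaus between feedings, staggered
extinctions (the fragile fermenters first, around the second feeding),
renewed growth within a few steps of each feeding, and a single
low-uptake, starvation-tolerant survivor (the Escherichia-like species).
Species rescued by the third feeding still starve out before step 184
because their tolerance plus decay time is shorter than the terminal
nutrient gap.

What the generator does *not* emulate: metabolic fluxes and nutrient
composition (a single pooled resource replaces hundreds of nutrients),
space, demographic micro-fluctuation during plateaus, and measurement
noise.  Passing tests on these series therefore show that the estimators
and the classification logic behave correctly on data with this phase
structure — not that the pipeline is robust to observational noise in
real longitudinal microbiome data.

Interventions:

* `disturb_coherence` multiplies each living species' count at each step
  of a window (default 109–128) by an independent factor uniform on
  [1 − jitter, 1 + jitter] (default jitter 0.3), rounded to a positive
  integer; extinct species stay at zero and steps outside the window are
  untouched.  The uniform multiplicative form is this package's choice of
  "random alteration".
* `enforce_crossfeeding` injects n_injected individuals of a metabolite
  hyper-producing variant of the producer species at the injection step.
  The producer fills a metabolite pool proportional to its abundance
  (hyper-producers count 1000-fold); the pool turns over in one step and,
  above a threshold, boosts the target's growth.  Thresholds are set so
  ordinary production never crosses but the injection always does, making
  the target's earliest abundance response fall exactly two steps after
  the injection — the mechanistic justification of d = 2.  The short
  crossfeeding scenario (38 steps, quarter refill, no feedings, high
  starvation tolerance) keeps all species on plateaus around the
  injection so the response is unambiguous.

## Effect classification

Features of a local signal are sharp changes: steps whose first
difference exceeds a threshold (default 0.5 nats — about half the typical
plateau-entry jump and well below the several-nat change-step outliers),
with nearby same-polarity candidates (gap ≤ 1 step) merged at their
strongest difference.  Given the same measure at three equally spaced
history lengths k₁ < k₂ < k₃ (spacing s), a feature at t in the
k₁-signal is *delayed* if same-polarity features recur at t + s and
t + 2s (within a 1-step tolerance), *immediate* if they recur at t in all
three, *ambiguous* if both hold (never resolved by guessing), else
*none*.  Filtering masks delayed and ambiguous extents but keeps the
values, so downstream consumers can render them as unreliable rather than
lose them.

The underlying geometry: AIS/CTE at step n + 1 condition on
x_{n−k+1} … x_n, so a prominent event at step e produces an echo at step
e + k, the first step where it leaves the conditioned window — on the
minimal one-jump series the echo lands at change_step + k exactly, which
is both a test oracle and the headline quantity the acceptance script
recomputes.

## Scenario experiments and problem sizes

The pipelines run AIS/CTE for all species at k = 10/15/20 on the 184-step
base run (the k-NN point clouds have T − k ≈ 170 points in up to
1 + k + 6(k−1) dimensions), which takes seconds per signal; the full
base scenario with 25-run averaging completes in well under a minute on
one core.  Tests use reduced averaging (2–10 runs) and the calibration
experiment uses 50 + 50 trials of length-100 series with 100 surrogates
each.  The coherence comparison is reported per seed and aggregated
across seeds: the disturbance effect is directional in expectation but
single realisations can invert at these sample sizes (observed ~1 in 10),
so the acceptance check asserts the seed-averaged contrast plus a clear
majority of individual seeds.

## Known limitations

* Estimates at k = 20 condition on ~135-dimensional joint spaces with
  ~165 points; values are usable for the *relative* feature analysis done
  here, not as calibrated information rates.
* The significance test permutes whole source blocks and therefore tests
  exchangeability against the observed destination — with strongly
  non-stationary series its null is approximate.
* Feature matching uses positions and polarities only; magnitudes are
  ignored, so a delayed echo superposed on an immediate change of the
  same sign is labelled ambiguous rather than split.
* The classifier requires exactly three equally spaced history lengths;
  unequal spacing is rejected, not approximated.
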