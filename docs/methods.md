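# Methods

## The test

Given equal-length series x and y, a truncation radius r and a
correlation statistic Θ, the engine computes
θ(δ) = Θ(x^trunc, y^trunc(δ)) for every shift δ ∈ [−r, r], counts the
shifts at least as strong as the unshifted alignment
(B, with δ = 0 always counted, so B ≥ 1), and reports u = B/(r+1)
together with min(u, 1). The decision rule is reject iff u ≤ α.
Validity — P(u ≤ α) ≤ α under independence — requires only that the
*shifted* series be strict-sense stationary; which series is shifted is
configurable (`surrogate_from`, default y). The test is deterministic:
no internal randomness anywhere in the decision path.

Tie handling in the B count is exact comparison (≥ for
similarity-oriented statistics, ≤ for error-oriented ones via the
orientation flag on `StatisticSpec`); floating-point ties count as ties,
which inflates B and is therefore conservative. Orientation inverts the
comparison rather than negating values so reported θ stays
interpretable. There is deliberately no tolerance parameter.

A technical caveat: the procedure probes dependence between y and the
*truncated* x window. When r is a large fraction of n most of x is
discarded, so a `LargeRadiusWarning` is emitted at r > n/3 (the
threshold is a judgement call; the test remains valid).

## Parameters that matter

* **r** (time steps). Controls both the surrogate count (2r) and the
  data left for the statistic (n − 2r). Only radii on the lattice
  r = j·m/α − 1 (j ≥ 1 an integer, m the number of lags tested) make the
  rejection region {u ≤ α} exactly attainable; `optimal_radius`
  evaluates the formula and `default_radius` picks the largest lattice
  radius at or below n/5 (but at least m/α − 1), following the
  observation that small radii win for short series.
* **l** (lag, default 0). The lag-l test pre-shifts to a hypothesized
  coupling delay. l must come from prior knowledge, never from the
  tested data — a data-chosen l makes rejection certain. The CLI has no
  scan-and-pick-best-lag mode for this reason. When l is only known to
  lie in a set, `multi_lag_tts` tests each lag at α/m (Bonferroni),
  which preserves validity.
* **α** (default 0.05 throughout).

## Correlation statistics

* `pearson` — |sample Pearson r|. Zero-variance windows raise a
  `DegenerateWindowError` naming the offending shift rather than
  returning 0, so calibration studies can count failures.
* `mi` — the Kraskov-Stoegbauer-Grassberger k-nearest-neighbour
  estimator I⁽¹⁾ (default k = 3), in nats. The joint space uses the
  maximum of the marginal distances; marginal counts use strict
  inequality at the k-th joint neighbour distance. Marginal metrics are
  pluggable; `mi-circular` pairs Euclidean distance on a linear variable
  with arccos(cos(α−β)) on a circular one. Optional seeded jitter
  (1e−10, off by default) can break exact duplicates; the benchmark
  systems are continuous so it is never needed there.
* `lsa` — local similarity: both series are normal-score transformed
  (average ranks → Gaussian quantiles), and the score is the maximal
  absolute partial sum of the products over contiguous intervals and
  delays |d| ≤ D, divided by n, computed by the standard positive/
  negative running-sum dynamic program. D defaults to 0 and is exposed.
* `ccm` — simplex cross-map skill: delay-embed x (dimension E = 2, lag
  τ = 1 by default), predict contemporaneous y from each point's E+1
  nearest neighbours with weights exp(−dᵢ/d₁) (indicator weights on
  exact ties at distance 0), and report the Pearson correlation of
  predictions with observations. The library is all embedded points;
  self-matches are excluded with exclusion radius 0; neighbour ties
  break to the lowest index.
* `median-pearson` / `median-lsa` — the base statistic per feature
  shared (by exact ID) between two feature-by-time tables, aggregated by
  the median (even counts: mean of the central pair). One test then
  covers a whole table.
* `sin_mod_transform` maps a circular direction to |sin φ| ∈ [0, 1] so
  that a linear correlation with e.g. speed becomes meaningful;
  `gap_fill` closes internal gaps by linear interpolation or seeded
  resampling from the feature's observed values (leading/trailing gaps
  must be trimmed first). The test engines refuse series with missing
  values, so filling is an explicit, auditable step.

## Comparator tests

* **Cyclic permutation**: all n − 1 rotations (deterministic,
  exhaustive).
* **Stationary block bootstrap**: restart probability p = 0.05 per step
  (geometric blocks, mean length ≈ 20), wrap-around continuation at the
  series end.
* **IAAFT**: 200 iterations, no early exit; output either the
  spectrum-matched iterate (`true_spectrum`, default) or the exact
  permutation (`true_amplitudes`).
* **Circularization** before wrap-around methods: trim to 1-based
  indices [k₁, k₂) minimizing Σᵢ₌₀..L (y_{k₂+i} − y_{k₁+i})² with
  L = 10, subject to k₁ ≤ 40 and n − L − k₂ + 1 ≤ 40; ties break to the
  lexicographically smallest pair (the choice is arbitrary but fixed).
  Cut points are selected on the surrogate-source series and applied to
  both.
* All stochastic surrogate tests use 499 surrogates by default and the
  classical p-value (N_as_strong + 1)/(N + 1).
* An iid **shuffle** is included purely as the negative control: it
  demonstrates the miscalibration on autocorrelated data that motivates
  everything else.
* **Parametric test**: the effective-sample-size t test. The variance
  of the sample correlation under independence is estimated from the
  lag-k autocovariances (1/(n−k) normalization, full-series mean); a
  negative estimate (possible in finite samples) falls back to 1/n,
  its no-autocorrelation value, and is flagged. The effective sample
  size m̂ = 1 + 1/σ̂²_ρ enters T = ρ̂√(m̂−2)/√(1−ρ̂²), two-tailed
  against Student t with m̂ − 2 degrees of freedom. Non-integer degrees
  of freedom are passed to the continuous t distribution — rounding
  would change p-values. The quarter-truncated variant zeroes
  autocovariance products at lags k > n/4 (strict inequality on the
  real value n/4); the full variant is the default. m̂ − 2 ≤ 0 is
  reported as p = 1 with a low-df flag rather than an exception.

The twin-surrogate method is excluded: it requires embedding-parameter
selection machinery (mutual-information lag minimization plus false
nearest neighbours) that is a project in itself.

## Benchmark systems

The generators emulate the standard calibration menu: AR(1) (φ = 0.5,
unit Gaussian noise, stationary initialization), the logistic map
(growth 3.8, uniform initial condition, 100-step burn-in), two
periodic-plus-noise constructions whose per-realization random phases
are what make them stationary (a sine with sawtooth-modulated noise and
a thresholded noisy sine), autocorrelated coin flips (a logistic-
squashed latent AR(1) heads probability, Bernoulli observation plus
measurement noise), a growth/collapse population observed from a
uniformly random offset within its period, a stochastic discrete-time
FitzHugh-Nagumo oscillator (Euler-Maruyama, dt = 0.1, a = 0.7, b = 0.8,
τ = 12.5, I = 0.5, burn-in 10⁴ steps — the discrete map is the model,
not an approximation target), a chaotic 4-species competitive
Lotka-Volterra system (the Vano et al. parameterization, Euler dt =
0.05, burn-in 5×10³ steps), and two nonstationary controls: a Gaussian
random walk and the AR(1) with an additive linear trend (slope 0.01 per
step by default). Numeric parameters not dictated by the qualitative
descriptions above were fixed once at field-conventional values and are
all exposed as keyword arguments.

Coupled systems for power studies: a bivariate AR pair with
x_t = φₓx_{t−1} + β·y_{t−lag} + ε (defaults φ = 0.5, β = 0.5, lag = 2,
unit noise; bidirectional mode adds the symmetric term, and the joint
parameterization is checked for companion-matrix spectral radius < 1),
and competition-style coupled logistic maps
x_{t+1} = x_t(rₓ − rₓx_t − β_yx·y_{t−lag}).

Every generator takes a seed and is exactly reproducible; independent
pairs come from two spawned seed streams with no shared state.

What the synthetic conditions do *not* capture: measurement
irregularity (uneven sampling), heavy-tailed noise, slowly drifting
parameters, and multi-lag interaction webs. Passing calibration here
shows the engine is correct under the stated stationarity condition; it
does not certify any particular real dataset as stationary — that
judgement (or a detrend) remains with the analyst.

## Experiment harness

`run_fpr_experiment` / `run_power_experiment` evaluate one (system,
test, statistic) cell: per-trial seeds are spawned deterministically
from the master seed (bit-for-bit reproducible, embarrassingly
parallel in principle), rates carry Wilson 95% intervals, and trials
that fail on degenerate windows are excluded and counted, with an abort
above 1% failures to guard against silent bias. The default trial count
is 2000 per cell — small enough for a laptop-scale run, with the
binomial margin made explicit everywhere a rate is compared to a
nominal level; full-scale counts are a config field.

## Numerical choices

* The Pearson shift profile has a vectorized path (sliding-window view,
  one matrix product) used for univariate |Pearson r|; it is tested
  against the generic per-shift loop. Exact ties between θ(δ) and θ(0)
  across the two paths could in principle differ in the last bit; with
  continuous data the event has probability ~0 and the B-count
  comparisons themselves are exact in both.
* In the detrend-retrend test the δ = 0 surrogate is taken to be the
  original truncated y (not residual-plus-trend recomposed), so the
  reconstruction identity holds exactly rather than to rounding.
* `optimal_radius` rounds j·m/α − 1 to the nearest integer and warns
  when the formula value was not an integer.
* BH adjustment clips superuniform inputs (u can exceed 1) at 1 before
  the step-up pass.

## Known limitations

* Phase-locked periodic pairs (and more generally noise-free
  deterministic systems whose whole orbit is predictable from any
  state) defeat the test: the statistic is equally strong at every
  shift, B saturates, and u is large regardless of dependence. This is
  visible with cross-map skill on noise-free coupled logistic maps —
  the skill is ≈ 1 at all shifts — and is intrinsic to any
  deterministic test with the same assumptions, not an implementation
  artifact.
* Power is generally below that of IAAFT or parametric competitors when
  their (stronger) validity conditions actually hold; the TTS test
  trades power for an assumption that is minimal and checkable.
* A multi-lag test over m lags needs n > 2(m/α − 1) points; short
  series simply cannot pay the Bonferroni bill, and `default_radius`
  raises a sized error saying so.
* No conditional-dependence (Granger-style) testing: the engine tests
  unconditional dependence only.
* Lag selection, stationarity certification and trend-model selection
  are out of scope by design; the analyst supplies them.
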