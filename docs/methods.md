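# Methods

## The statistical families

All five candidate laws are discrete distributions on integer support
{i_min, …} (i_min = 1 throughout unless stated; an optional finite cap is
used when fitting model output on {1..N}).  Unnormalized weights:

| family                 | weight w(i)                  | parameters |
|------------------------|------------------------------|------------|
| truncated power law    | i^−α e^−λi                   | α ≥ 0, λ ≥ 0 |
| pure power law         | i^−α                         | α > 1 (unbounded support) |
| exponential            | e^−λi                        | λ > 0 |
| stretched exponential  | i^(β−1) e^(−λ i^β)           | λ > 0, β > 0 |
| lognormal              | (1/i) exp(−(ln i − μ)²/2σ²)  | μ > 0, σ > 0 |

The exponential and stretched-exponential forms are the standard discrete
conventions of the heavy-tailed fitting literature; the lognormal location
is constrained positive.  Normalizers are computed by direct summation with
an explicit analytic tail bound (stopping when the bounded remainder is
below 10⁻¹³ of the running sum); the pure power law uses the Hurwitz zeta
closed form, and the truncated power law falls back to the polylog
Li_α(e^−λ) (via mpmath) when λ < 10⁻⁴ would make direct summation too long.
The pure power law is the λ = 0 subcase of the truncated family, which is
why the fitted truncated likelihood can never fall below the pure-law
likelihood on the same data — a property the tests assert.

Fitting is maximum likelihood over each family's parameter box
(L-BFGS-B from several moment-based starts; data compressed to unique
values with counts, so the cost is independent of sample size).  The 95%
interval for the power-law exponent comes from the observed information
(numerical Hessian of the negative log-likelihood at the optimum).
Optimizer failure is flagged on the result, never silent.  i_min defaults
to 1 — whole distributions are fitted; automatic x_min selection is
deliberately out of scope.

Sampling is inverse-CDF over a table extended until the residual tail mass
is below 10⁻¹⁰ (capped at 10⁶ support points, residual folded into the last
entry) — a per-draw bias of order 10⁻¹⁰, irrelevant at the 10⁵-draw scales
used here.

## Model selection

For two fitted families the comparison statistic is

    R = Σᵢ [ln p₁(xᵢ) − ln p₂(xᵢ)],
    σ² = (1/n) Σᵢ (dᵢ − d̄)²  with dᵢ the pointwise log-ratio,
    p  = 2 Φ̄( |R| / (σ √n) ).

Positive R favours the first family; the sign is reported as decisive only
when p < 0.05 (configurable), otherwise "indeterminate".  The same
normalized statistic is used for the nested truncated-vs-pure comparison
(a one-sided option exists but is off by default).  σ = 0 with R = 0
(identical models) yields p = 1.  For weighted data (model output) n is the
total weight and all moments are weight-averaged.

Per-group analysis fits all five families within each metagenome (or
habitat), reports the winner by log-likelihood, whether a power-law family
won, and whether every pairwise comparison against the winner is
individually significant; groups below the observation floor (default 30
arrays) are flagged `insufficient` rather than dropped — small metagenomes
genuinely cannot discriminate these families.

## The Markov chain

Classes i = 1..N (default N = 1000) hold abundances Fᵢ summing to the
carrying capacity F_const (default 10⁶; the stationary distribution is
invariant to its value).  One time step is two half-steps.

**Infection.**  With probability p a cell meets a phage.  Survival and gain
depend on whether the array holds a matching spacer (probability qᵢ):
perfect match (probability h): survive, gain k ~ P(μ_n); imperfect match:
survive with probability g, gain k ~ P(μ_m); no match: survive with
probability s, gain k ~ P(μ_k).  Parameters obey s ≤ g ≤ h, and priming
motivates μ_n ≈ μ_m ≫ μ_k (defaults keep 100 μ_k = μ_m = μ_n).  All gain
and loss laws P(μ, ·) are geometric with mean μ,
P(k) = (1/(1+μ)) (μ/(1+μ))^k on k ≥ 0 — the maximum-entropy discrete law
with the stated mean, whose mode at 0 matches the observation that most
loss events remove 0–1 spacers.  Zero-gain survivors stay on the diagonal
(switchable via `include_zero_gain`).  The row deficit of the resulting
substochastic matrix A¹ is the per-class death probability.

**Boundary at N.**  Gain mass that would exceed class N is, by default,
*discarded* — counted as death and compensated by replication
(`boundary="discard"`).  The alternative `"accumulate"` (pile the excess
into class N) is available but makes class N quasi-absorbing in the
rich-get-richer regime: death at i = N scales as p(1−q_N)(1−s) ≈ 10⁻⁴
while inflow is steady, so essentially all stationary mass ends at the cap,
which contradicts the decaying distributions the model is meant to produce.
Under "discard" the cap behaves as a hard viability limit and the
stationary distribution dies off well before N in all regimes studied.
Loss mass below class 1 always accumulates in class 1 (class 1 is not
absorbing — its death rate is the largest of all classes).

**Replication.**  Survivors replicate at rates νᵢ scaled by the factor

    N_ν = (F_const − Σ Fᵢ(t+½)) / (Σ νᵢ Fᵢ(t+½)),

the unique value restoring the total to F_const: each survivor of class i
contributes N_ν νᵢ daughters.  The parent keeps its array; the daughter
loses ℓ ~ P(S_L · i) spacers (S_L is the expected lost fraction).  The
replication matrix is A² = I + N_ν D with D[i, j] = νᵢ P(S_L i, i−j),
row sums exactly 1 + N_ν νᵢ.

**Profiles.**  qᵢ: constant, linear (i−1)/N, or logistic (monotone
increasing, configurable midpoint/steepness).  νᵢ: constant, linear
(N+1−i)/N, or Gaussian exp(−(i/w)²).  Constant profiles give light-tailed
unimodal stationary states; increasing qᵢ alone concentrates mass at high
i; decreasing νᵢ alone gives a left-skewed, non-heavy-tailed state; the
truncated-power-law regime requires both.

**Stationarity.**  Iteration from a uniform state, recomputing N_ν each
step, until the normalized distribution moves less than `tol` = 10⁻¹⁰ in L1
(cap 10⁴ iterations; typically 2–10·10³ are needed, with critical slowing
near the bifurcation described below).  Independently, the stationary state
is the left principal eigenvector of A¹A²(N_ν\*) at eigenvalue 1; an
eigenvalue off 1 by more than 10⁻⁶ signals a non-equilibrium N_ν\* and is
an error.  The p = 0 chain (no phage, hence no deaths, hence N_ν = 0 and
A = I) is reported as degenerate rather than solved.  The two routes agree
to L1 ≈ 10⁻⁸ in the heavy-tail regime — one of the acceptance checks.

**Fitting model output.**  The stationary probabilities are converted to
integer cell counts in a 10⁶ population (classes under one cell are empty)
and fitted by weight-aware MLE on {1..N} — deterministic, no resampling
noise.

## The bifurcation of the stationary exponent

The fitted exponent α responds smoothly to the loss fraction S_L and gain
mean μ_n over most of the regime (α non-decreasing in S_L, non-increasing
in μ_n — asserted by the sweep checks), but the regime ends at a sharp
critical manifold: just past it the distribution collapses onto the lowest
classes with a steep cutoff (λ jumps from ~10⁻³ to ~0.5).  With the linear
profiles and the perfect-matching base parameters (p = 0.7, h = 1, s = 0.4,
μ_n = μ_m = 10, μ_k = 0.1) this implementation places the critical point at
S_L\* ≈ 0.134: α rises 1.00 → 1.9+ as S_L goes 0.125 → 0.133, then drops to
the collapsed branch at S_L = 1/7.1 ≈ 0.141.  The location of this critical
manifold is sensitive to discretization conventions that the model's
published description leaves open (the exact discrete form of the
"exponential" gain law, the fate of zero-gain encounters, the cap rule);
exploratory variants moved S_L\* by ±10% without changing the qualitative
picture.  Consequently, of the four published (parameter → α) points probed
by the acceptance suite, the two on the near side of the critical manifold
reproduce (α ≈ 1.00 vs 1.03; extrapolation 11,211 vs ≈ 11,300), while the
two straddling points land on the wrong branch here (α = 1.13 vs 3.1;
α ≈ 2.31 vs 1.85/2.57) — documented as failing checks rather than tuned
away, since no single convention reproduced all four simultaneously.

## Synthetic data

The generator emulates a metagenome collection: per-sample array counts
drawn log-uniformly from 10–10⁴ (matching the orders-of-magnitude spread of
real collections), habitats assigned from a 13-label vocabulary by a
proportion mix, per-array counts iid from the configured law (default the
pooled empirical law α = 2.57, λ = 0.004).  It deliberately omits features
of real data — habitat- or phylogeny-correlated exponents, per-sample law
heterogeneity, detection artifacts of upstream CRISPR callers, multiple
arrays per genome — so passing tests demonstrate correctness of the
statistical machinery on iid draws, not robustness to those real-world
structures.  Negative controls: discrete lognormal, discrete exponential,
and rounded positive Gaussian.

## Numerical and interface conventions

* Matrices are row = source class, column = destination.
* Conservation Σ Fᵢ = F_const holds to 10⁻⁹ relative after every full step
  by construction of N_ν (asserted each iteration in the tests).
* log-pmf of points outside the support is −inf; pmf is 0.
* Degenerate inputs fail loudly: constant data, too few observations
  (< 30 by default), extinct populations, non-equilibrium eigen scaling.
* All randomness flows through explicit integer seeds; identical seeds give
  identical datasets, fits, and reports.  Stationary-model fits involve no
  randomness at all.
* Problem sizes used by the shipped checks: N = 1000 for the published
  parameter points and cross-method agreement, N = 100–200 for regime and
  conservation properties, 10⁵ draws for recovery and selection checks —
  each chosen as the smallest size at which the corresponding claim is
  stable.

## Known limitations

* Spacer identity, diversity, and position effects are outside the model
  (classes count spacers only), as are phage population dynamics and
  spatially structured (abortive-infection-like) interpretations.
* The loglikelihood-ratio p-value is asymptotic; at small n (tens of
  arrays) the per-group analysis correctly reports most comparisons as
  insufficient or indeterminate.
* Near the critical manifold the iteration slows down (the subdominant
  eigenvalue approaches 1); runs capped at `max_iter` return
  `converged=False` and should be treated as unresolved rather than
  stationary.
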