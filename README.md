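# spacerlaw

Heavy-tailed statistics and population dynamics of CRISPR spacer-array
lengths.

CRISPR arrays store phage-derived spacers; the number of spacers per array,
pooled over many microbial genomes or a metagenome, follows a truncated
power law

    p(i) ∝ i^(−α) e^(−λ i),   i = 1, 2, …

with exponents around α ≈ 2–3 and a weak exponential cutoff λ ≈ 0.004.
`spacerlaw` is a toolkit for working with this observation from both ends:

* **Statistics.** Discrete maximum-likelihood fitting of the truncated power
  law and its standard competitors (pure power law, exponential, stretched
  exponential, lognormal) to per-array spacer counts, with Vuong-style
  loglikelihood-ratio model selection (statistic R = Σ ln p₁(xᵢ) − ln p₂(xᵢ),
  normal-approximation p-value) — pooled across a collection or per
  metagenome.
* **Mechanism.** A discrete-time Markov-chain model of a bacterial
  population under phage pressure.  Cells sit in classes i = 1..N by array
  length; each step is an infection stage (death or geometric spacer gain,
  with immune efficiency qᵢ increasing in i) followed by a replication stage
  (daughters lose a geometric number of spacers with mean S_L·i, replication
  rate νᵢ decreasing in i, rescaled by N_ν to hold the population at a
  carrying capacity).  When qᵢ rises and νᵢ falls with i — richer arrays
  survive better but replicate slower — the stationary class distribution
  F\* is itself a truncated power law.
* **Synthetic data.** A generator for metagenome collections with the
  assumed statistical structure (log-uniform sample sizes, habitat labels,
  configurable generator law) plus non-heavy-tailed negative controls, so
  the full pipeline is testable without any external downloads.

## Worked example

Generate a synthetic collection of 50 metagenomes whose pooled counts follow
the empirical pooled law (α = 2.57, λ = 0.004), then fit and rank the
candidate families:

```
$ spacerlaw synth --out demo/data --set n_metagenomes=50 --set seed=7
$ spacerlaw fit --out demo/fit --set input=demo/data/dataset.tsv
INFO spacerlaw.pipeline: loaded 69723 arrays from 50 samples
```

`demo/fit/report.json` then contains (abridged):

```
best_family: truncated_powerlaw
alpha = 2.5774   (95% CI 2.5600 – 2.5948)
lam   = 0.0031
ranking (R > 0 favours the truncated power law):
  exponential            R = 15051.6   p = 1.2e-86
  stretched_exponential  R =   697.5   p = 2.3e-56
  lognormal              R =  4746.8   p < 1e-300
  powerlaw               R =     4.2   p = 0.11   (indeterminate)
```

The generating exponent is recovered inside its confidence interval; every
alternative family is rejected except the pure power law, which at this
cutoff (λ ≈ 0.003) is only weakly distinguishable — exactly the behaviour
expected of a shallow exponential correction.

Running the mechanistic model in its heavy-tail regime (linear profiles
qᵢ = (i−1)/N, νᵢ = (N+1−i)/N, N = 1000):

```
$ spacerlaw simulate --out demo/sim --set p=0.7 --set h=1.0 --set s=0.4 \
      --set g=0.7 --set mu_n=10 --set mu_m=10 --set mu_k=0.1 \
      --set S_L=0.125 --set N=1000 --set eigen_check=true
INFO spacerlaw.pipeline: stationarity: 6159 iterations, converged=True, N_nu*=0.700898
INFO spacerlaw.pipeline: eigenvector cross-check: L1 distance 1.27e-08
```

The stationary distribution fits a truncated power law with α = 1.0024,
λ = 0.0025, and the iterative solution agrees with the left principal
eigenvector of the full-step transition matrix to L1 ≈ 10⁻⁸.

The longest array expected anywhere on Earth, scaling the pooled law to
~10³⁰ prokaryotic cells:

```
$ spacerlaw extrapolate --alpha 2.57 --lam 0.004 --population 1e30
11211
```

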