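# Methods

## Model and assumptions

Lifetimes are i.i.d. Chen(θ, λ) with cdf `F(x) = 1 − exp(θ(1 − e^{x^λ}))`.
The shape λ governs the hazard geometry (bathtub for λ < 1, increasing for
λ ≥ 1); the scale θ enters the censored likelihood linearly through the
sufficient statistic `T = Σ e^{xᵢ^λ} + (n−r)e^{τ^λ} − n`.  All censored-data
estimators in the package treat **λ as known** — in practice fixed at a
complete-data estimate — because the double-exponential dependence on λ
admits no conjugate analysis.  Estimating λ from censored data, interval
estimation, and censoring schemes other than type-I are out of scope.

Type-I censoring assumes a fixed, non-random termination time τ and
independent items; an observation equal to τ counts as observed (closed
interval `(0, τ]` — the packaged data have no value at 10 or 20, so the
real-data counts do not depend on this convention).  Ties among failure
times are kept; the likelihood is exchangeable.  The combinatorial factor
`n!/(n−r)!` is dropped from the log-likelihood as a constant.

## Estimators

* **MLE** `θ̂ = r/T`, undefined at r = 0 (raised as an error; the censoring
  time must be large enough that some failure is observed).  Reliability
  and hazard MLEs are plug-ins.
* **Bayes (BSEL)** with Gamma(a, b) prior: posterior Gamma(r+a, b+T);
  the balanced squared-error-loss rule is `ω·anchor + (1−ω)·posterior
  expectation`, the anchor being the MLE plug-in throughout (no other
  anchors are exposed).  The reliability estimator's posterior part is the
  Gamma moment generating function `((b+T)/(b+T+T*))^{r+a}` with
  `T* = e^{t^λ} − 1`; the hazard factorizes exactly as
  `λt^{λ−1}e^{t^λ} · θ̂_BS`.
* **E-Bayes**: the hyper-prior expectation of the Bayes rule over
  `(a, b) ∈ (0,1) × (0,s)`, with `a ~ Beta(u, v)` independent of `b` whose
  density is uniform (π1), `2(s−b)/s²` (π2) or `2b/s²` (π3).  The support
  `a < 1` keeps the conditional Gamma prior decreasing in θ.  For θ and h
  the expectation separates into `(r + u/(u+v)) · E_family[1/(b+T)]`, with

      E_π1 = ln((s+T)/T)/s,
      E_π2 = 2((s+T)ln((s+T)/T) − s)/s²,
      E_π3 = 2(s − T·ln((s+T)/T))/s².

  Note the first factor is `r + E[a] = r + u/(u+v)`, the exact hyper-prior
  mean; with the package's default u = v = 0.5 it equals r + ½.  For R(t)
  the inner Beta average is the Kummer function `M(u, u+v; c)` at
  `c = ln((b+T)/(b+T+T*)) ≤ 0`, leaving a smooth 1-D integral over b.

### Ordering of the hyper-prior families

Because `1/(b+T)` is decreasing in b, the family weighting large b (π3)
yields the smallest θ and hazard estimates and the family weighting small b
(π2) the largest: for `0 < s < T`,

    θ̂_EBS3 < θ̂_EBS1 < θ̂_EBS2   (and identically for h),
    R̂_EBS2 < R̂_EBS1 < R̂_EBS3   (reliability is increasing in b),

with π1 the exact midpoint for θ/h (an algebraic identity of the three
weights) and the midpoint of R to quadrature accuracy.  All pairwise gaps
are O(1/T²) and vanish as T grows, so with abundant data the choice of
family is immaterial.  These directions are verified in the test suite
against brute-force double-integral oracles; published statements of the
θ ordering vary in direction, and the package asserts the one the oracle
proves.

## Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ω | 0.3 (study, real data), 0.0 (library default) | BSEL anchor weight; 0 recovers pure posterior-mean Bayes |
| (a, b) | Prior I (2.0, 1.0), Prior II (1.5, 0.5) in the study; (0.1, 0.1) for the real data | informative pair used in the comparison study; near-noninformative for data analysis |
| (u, v) | (0.5, 0.5) | symmetric Beta hyper-prior on a, mean ½ |
| s | 0.5 (alternative 10) | range of the b hyper-prior; s < T keeps the family ordering strict |
| evaluation time t | 0.5 (study), 15 months (real data) | where R and h are reported |
| replicates | 10,000 | study size; Monte Carlo SE of an AE ≈ sd/100 |

A Gamma prior with a ≥ 1 is accepted but warns, since the prior is then not
a decreasing density in θ (the informative study priors deliberately
violate that condition).

## Numerical choices

* **Log-scale distribution functions**: survival/cdf via
  `expm1`/`log1p`; for very large `t^λ` the survival saturates to 0 and the
  cdf to 1 without overflow warnings.  `pdf`/`hazard` reject t = 0 when
  λ < 1 (a pole) rather than returning `inf`.
* **Complete-data MLE**: profile `θ(λ) = n/Σ(e^{xᵢ^λ} − 1)`; the 1-D profile
  likelihood is first scanned on a 200-point log grid over the λ bounds
  (default `(1e-3, 10)`) to bracket the optimum away from the
  overflow-penalty plateau at large λ, then refined by bounded scalar
  minimization to `xatol = 1e-12`.
* **E-Bayes reliability, scalar path**: adaptive Gauss–Kronrod quadrature
  over b on (0, s), `epsrel 1e-10`, `epsabs 1e-12`, with scipy's `hyp1f1`
  for the Kummer factor (argument always ≤ 0, where the routine is
  accurate); a Kummer-transformation fallback guards non-finite returns.
* **E-Bayes reliability, batch path** (simulation engine): tensor
  Gauss–Jacobi (24 nodes, exact for the Beta(u, v) average over a — no
  Kummer calls) × Gauss–Legendre (32 nodes over b) quadrature, vectorized
  across replicates.  Both integrands are analytic, so the rule is
  accurate to ~1e-12; agreement between the two routes is tested to 1e-8.
* **Random numbers**: every sampler takes an explicit seed or Generator;
  replicate i of a study draws from `SeedSequence(seed, spawn_key=(i,))`,
  so single replicates are reproducible in isolation and studies are
  deterministic bit-for-bit.

## The simulation engine (synthetic data)

Each replicate draws n lifetimes by inverse-transform sampling of the Chen
quantile function, censors them at τ, and applies every estimator to the
same sample (common random numbers across methods, so method contrasts are
not diluted by sampling noise).  Replicates with r = 0, where no estimator
exists, are redrawn from the same per-replicate stream and counted; at the
default settings (`P(X ≤ 1.5) ≈ 0.70`) this has probability ≈ 4e-11 per
replicate and never triggers.  Summaries are the average estimate (AE), the
mean squared error about the configured truth (MSE), and the Monte Carlo
standard error of the AE — reported explicitly because reproduction checks
need it.

The generator emulates exactly the idealized study conditions: i.i.d.
lifetimes from the assumed family, a deterministic censoring time, and a
correctly specified, known shape λ.  It does not emulate model
misspecification, covariates, random or staggered entry, or measurement
rounding — so passing tests demonstrate correctness of the estimators
under the model, not robustness of the model on real data.

Published comparison tables are themselves 10,000-rep Monte Carlo means;
reproduction tests therefore compare at `3·√2·SE` (the 3-sigma band of a
difference of two independent equal-size Monte Carlo means) plus the
half-ulp of the printed 4-decimal rounding.

## Real-data workflow

The packaged fixture (148 renal-graft survival times in months,
checksum-pinned) is analysed by: complete-data joint MLE
(θ̂ = 0.042901, λ̂ = 0.386321, bathtub shape); censored re-analyses at
τ = 10 (r = 52) and τ = 20 (r = 93) with λ fixed at the **full-precision**
complete-data MLE (the rounded 0.3863 can be supplied via
`RealDataConfig(lam=...)`, and reproduces the published 5-decimal θ digits
exactly — the published table evidently used the rounded value);
estimation of θ, R(15) and h(15) by all methods; and "approximated MSEs",
squared deviations from the complete-data plug-ins treated as truth.  The
BSEL weight and hyper-parameters for this analysis are not uniquely
determined by the published digits; the defaults ω = 0.3,
prior (0.1, 0.1), (s, u, v) = (0.5, 0.5, 0.5) are documented assumptions,
and the E-Bayes digits of the published real-data table are not
reproduction targets.

## Known limitations

* λ must be supplied (or estimated from complete data); no censored-data
  inference for the shape.
* No interval estimates or credible sets — point estimation only.
* The E-Bayes reliability quadrature assumes s is moderate (the b-integrand
  is evaluated densely on (0, s)); extremely large s with tiny T would
  warrant a change of variables.
* Goodness of fit of the Chen family to user data is not assessed.
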