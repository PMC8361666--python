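# Methods

## Model

The random-effects model for meta-analysis: study-specific true effects
θᵢ ~ N(θ, τ²) independently for i = 1…n, and observed effects
Yᵢ | θᵢ ~ N(θᵢ, σᵢ²). The within-study variances σᵢ² are treated as fixed
and known everywhere; marginally Yᵢ ~ N(θ, σᵢ² + τ²). All inference plugs
the estimate τ̂² in wherever τ² appears and deliberately ignores its
sampling uncertainty — that is the conventional practice whose consequences
the simulation engine quantifies.

Pooling uses inverse-variance weights ŵᵢ = (σᵢ² + τ̂²)⁻¹:
θ̂ = Σŵᵢ Yᵢ / Σŵᵢ with Var(θ̂) = 1/w, w = Σŵᵢ.

## Study-specific estimates and the three variance formulae

The conditional distribution of θᵢ given Yᵢ under the bivariate-normal
representation yields the empirical Bayes estimate
θ̂ᵢ = B̂ᵢθ̂ + (1−B̂ᵢ)Yᵢ with B̂ᵢ = σᵢ²/(σᵢ²+τ̂²); the variance-components
(mixed-model) representation yields the BLUP γ̂ᵢ = (1−B̂ᵢ)(Yᵢ−θ̂) with
θ̂ᵢ = θ̂ + γ̂ᵢ. The two derivations give the same number, which is why the
package exposes a single `blup_estimates`.

Three variances can accompany θ̂ᵢ (all implemented in `shrinkage`):

* **crude** — V = σᵢ²τ²/(σᵢ²+τ²), the conditional variance of θᵢ | Yᵢ with
  all parameter uncertainty ignored. Its precision is the sum of the within-
  and between-study precisions. It degenerates to zero when τ̂² = 0, a
  common estimate in practice, so the package attaches a warning there.
* **raudenbush** (default and recommended) —
  V = σᵢ²τ²/(σᵢ²+τ²) + (1/w)·σᵢ⁴/(σᵢ²+τ²)², the crude variance plus a term
  for the uncertainty in θ. Equivalently Var(θ̂ᵢ − θᵢ), the BLUP prediction
  error variance. It is bounded above by σᵢ² (equality exactly at n = 1),
  collapses to 1/w at τ² = 0 and to the crude variance as w → ∞, and tends
  to σᵢ² as τ² → ∞.
* **quan** — V = τ⁴/(σᵢ²+τ²) + (1/w)·σᵢ²(σᵢ²+2τ²)/(σᵢ²+τ²)². This is
  Var(θ̂ᵢ) itself, the variance appropriate for inference about the
  *average* effect θ via the pivot θ̂ᵢ − θ. It is implemented for
  comparison and clearly labelled as ill-suited to θᵢ: in the large-w limit
  it *decreases* in σᵢ² (small studies get narrow intervals) while the
  Raudenbush limit increases, and the two coincide only when σᵢ² = τ².

The decomposition Var(θ̂ᵢ−θᵢ) = Var(θ̂ᵢ) + Var(θᵢ) − 2Cov(θ̂ᵢ,θᵢ) is
exposed as `blup_decomposition_terms`; a property test asserts the terms
sum to the Raudenbush variance to 1e−12 relative error.

Study-specific prediction intervals are θ̂ᵢ ± z₀.₉₇₅√V with the normal
quantile computed to full double precision (1.959964…, not the rounded
1.96). Under the Knapp–Hartung adjustment the 1/w factor inside the
Raudenbush/Quan second term is replaced by q/w, where
q = Σŵᵢ(Yᵢ−θ̂)²/(n−1); the crude formula has no such term and is
unchanged. The quantile stays normal by default because the t pivot of the
adjustment is defined for θ̂, not θ̂ᵢ; `kh_t=True` switches to t₍ₙ₋₁₎ for
users who prefer a conservative pivot. q is untruncated by default
(matching common software); `truncate=True` floors it at one.

## Pooled intervals

Confidence interval for θ: θ̂ ± z√(1/w), or θ̂ ± t₍ₙ₋₁₎√(q/w) with the
Knapp–Hartung adjustment. Prediction interval for the true effect of a
new study: θ̂ ± t₍ₙ₋₂₎√(1/w + τ̂²), hard-requiring n ≥ 3 since the t
distribution needs at least one degree of freedom; the unscaled 1/w is
used inside the root even when the Knapp–Hartung scale is available,
matching the printed definition of this interval.

## Between-study variance estimators

* **DerSimonian–Laird**: τ̂² = max(0, (Q − (n−1))/C) with Q the
  fixed-effect weighted sum of squares and C = Σwᵢ − Σwᵢ²/Σwᵢ, wᵢ = 1/σᵢ².
  One-step, truncated at zero.
* **Paule–Mandel**: the root of Q_gen(τ²) = Σ(σᵢ²+τ²)⁻¹(Yᵢ−θ̂(τ²))² = n−1,
  or zero when Q_gen(0) ≤ n−1. Q_gen is monotone decreasing, so a
  bracketing root-finder is robust: the initial upper bound is
  10·(max σᵢ² + sample variance of Y), doubled up to 60 times if needed,
  and the root is polished essentially to machine precision so the moment
  condition itself holds far inside the nominal tolerance (default 1e−10
  on τ²). A by-product worth knowing: at the PM estimate the
  Knapp–Hartung scale is exactly 1.
* **REML**: bounded scalar maximization of the restricted log-likelihood
  −½Σlog(σᵢ²+τ²) − ½log Σ(σᵢ²+τ²)⁻¹ − ½Σŵᵢ(Yᵢ−θ̂)² over [0, U] (same U
  policy, tolerance 1e−8, iteration cap 500). Chosen over fixed-point
  iteration for guaranteed convergence on a bounded interval;
  non-convergence is flagged on the returned estimate, never raised.
  A grid-search oracle test confirms the optimizer to 1e−3.

All estimators require n ≥ 2 and raise a clear error below that.

## Simulation engine

The generator emulates two study designs:

* **normal**: θᵢ ~ N(0, τ²), σᵢ² ~ Uniform(0.05, 1), Yᵢ ~ N(θᵢ, σᵢ²). The
  random-effects model holds exactly, so deviations from nominal coverage
  isolate the cost of estimating τ².
* **binary**: θᵢ is a true log odds ratio; the control arm draws
  xᶜ ~ Binomial(n_arm, π_c), the experimental arm uses
  π_e = π_c e^θᵢ/(1−π_c+π_c e^θᵢ), and (Yᵢ, σᵢ²) are the log odds ratio
  and its standard variance after adding 0.5 to **all four** cells of every
  table (unconditionally, which also keeps zero-cell tables finite). Here
  the normal model is only an approximation, so coverage deviations mix
  τ²-estimation error with approximation error; both shrink with larger
  arms (200 vs 50) and commoner events (π_c = 0.5 vs 0.1).

Heterogeneity is calibrated through I² = τ²/(s²+τ²) with s² the typical
within-study variance: (b−a)/ln(b/a) = 0.31712 (reciprocal of the expected
precision) for the uniform design, and 2/(n_arm·π_c(1−π_c)) for the binary
design (the closed-form log-odds approximation with π_e ≈ π_c, exact at
μ = 0; a simulation-based alternative gives very similar values and is not
used). The unrounded s² feeds the inversion τ² = I²s²/(1−I²), giving
τ² ∈ {0, 0.035, 0.106, 0.317, 0.951, 2.854} to three decimals at the six
I² levels.

Condition grids are full factorials — n ∈ {5, 20, 80} × I² ∈ {0, 0.1,
0.25, 0.5, 0.75, 0.9}, crossed with π_c ∈ {0.1, 0.5} × n_arm ∈ {50, 200}
for the binary design — 18 and 72 cells with μ = 0 throughout (for the
normal design μ is a pure location shift; for the binary design it is held
at zero to keep the grid manageable).

`run_coverage_study` reports the per-meta-analysis mean coverage averaged
over replications, coverage conditional on the study with the largest θᵢ
(the first study when τ² = 0, where all θᵢ coincide), coverage conditional
on the largest σᵢ² (normal design only — the binary design has no separate
within-study-variance draw), mean interval width, and the Monte-Carlo
standard error (SD of per-replication mean coverage / √reps). Width is
recorded but not interpreted when coverage is off-nominal, since width
comparisons are only meaningful at comparable coverage. Replications where
τ² estimation fails to converge are logged and use the last iterate,
never silently dropped.

**Seeding.** Each condition draws its replication streams from
`SeedSequence([base_seed, condition_index])` spawned per replication:
results are bit-for-bit reproducible, conditions never share streams, and
replications are independent.

**Problem sizes.** The published design runs 10,000 replications per
condition; the package's documented desk-scale setting — used by the
test-suite and the acceptance script — is 2,000, at which the Monte-Carlo
SE of a coverage near 0.95 is about 0.001 for n = 20 studies, ample for
every qualitative and 3-SE comparison made.

## What the generator does and does not emulate

It reproduces the stated sampling processes exactly, so passing tests show
the estimators and intervals behave correctly *under the model* (and under
binomial sampling for the binary design). Real meta-analyses additionally
feature estimated within-study variances correlated with effects,
non-normal true-effect distributions, selective publication, and dependent
estimates — none of which are generated here, so nominal coverage in these
simulations does not certify nominal coverage in the field.

## Numerical choices and degenerate inputs

* Normal/t quantiles at full double precision throughout.
* τ̂² truncation at zero in all estimators; B̂ᵢ ∈ [0,1] by construction.
* τ̂² = 0 with the crude formula yields zero-width intervals; a
  `ZeroTau2Warning` is attached rather than an error because the fit
  itself is valid.
* A single study is accepted by the fit (θ̂ = Y₁, Var = σ₁² + τ²) but not
  by any τ² estimator, the Knapp–Hartung scale (n ≥ 2) or the new-study
  interval (n ≥ 3).
* Ties in the largest-θᵢ / largest-σᵢ² conditioning resolve to the first
  maximizer; at τ² = 0 the largest-θᵢ metric uses the first study by
  definition.

## Known limitations

Meta-regression, multivariate models, generalized linear mixed models,
fully Bayesian intervals, variance formulae accounting for τ̂² uncertainty,
confidence intervals for τ² itself, and additional τ² estimators (Hedges,
Sidik–Jonkman, …) are out of scope. The Quan formula is provided for
methodological comparison only; the forest plot draws the shrinkage layer
in addition to, never instead of, the conventional one.
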