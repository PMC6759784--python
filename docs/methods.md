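# Methods

## Model

Each of K tests carries a binary indicator θ_j (1 = alternative true) and an
observed statistic X_j.  Inference targets the exact posterior over
θ ∈ {0,1}^K,

p(θ | X) ∝ p(X | θ) p(θ),

enumerated over all 2^K configurations in log space (log-sum-exp); the
per-test marginal p(θ_j = 1 | X) sums the joint mass over configurations
with bit j set, and the decision rule accepts the alternative when the
marginal strictly exceeds a threshold τ (default 0.5, i.e. "the alternative
is more probable than the null"; boundary ties retain the null).  Exactness
is the point: no MCMC or variational step intervenes between model and
number, at the cost of a hard K ≤ 20 cap (2^20 ≈ 10^6 configurations).

Dependence enters in exactly two places, and the package keeps them
separate because they behave differently:

* **Prior association** — p(θ) need not factorize.  The canonical family is
  a common-cause mixture: with probability ρ all indicators copy one shared
  Bernoulli(π) draw, otherwise they are i.i.d. Bernoulli(π).  This yields
  margins exactly π and pairwise correlation exactly ρ, spanning
  independence (ρ=0) to a single pooled hypothesis (ρ=1).  The mixture
  cannot express negative association; `ExplicitTablePrior` and the K=2
  `PairwisePrior` (moment-parameterized, rejected outside the Fréchet
  bounds) cover that case.
* **Residual dependence** — p(X | θ) need not factorize either, e.g. when
  the same subjects are analyzed repeatedly.  On the z scale the statistics
  are jointly multivariate normal with mean μ∘θ and correlation matrix R.

## Evidence models

The sampling distributions are deliberately simple, stated defaults rather
than estimates:

| scale | null | alternative | default |
|---|---|---|---|
| z | N(0,1) | N(μ_j, 1) | μ_j = 2 |
| p | Uniform(0,1) | Beta(a_j, 1), density a x^(a−1) | a_j = 0.1 |

Unit variance under both hypotheses (shift-only alternative) keeps the
collider-path analysis interpretable as two association directions.  μ = 2
corresponds to a study with roughly 50% power at the two-sided 5% level —
a realistic epidemiological stratum.  Residual dependence is supported only
on the z scale (Gaussian with correlation R); combining p-scale margins
with R raises an error rather than silently approximating a copula.

## Independence reduction

When the prior factorizes and R is the identity, the marginalization
collapses algebraically to the single-test posterior
π f₁(x_j) / (π f₁(x_j) + (1−π) f₀(x_j)).  `marginal_posterior` implements
this reduction as an explicit code path (delegating to
`single_test_posterior`, computed as a logistic of the log odds), so in the
fully independent case the result is identical to the single-test value by
construction and provably invariant to other tests' data; the test suite
additionally verifies that full enumeration agrees with the reduction to
1e−12.  This is the formal content of "adjusting independent tests for one
another is irrelevant".

## Post-hoc Wald p-values

For a ratio estimate with a two-sided CI at level γ, the log-scale standard
error is (ln CI⁺ − ln CI⁻) / (2 z₍(1+γ)/2₎) with the exact normal quantile
(1.959964 at 95%, not 1.96 — though at two-decimal reporting the packaged
table is identical under either).  The reconstruction applied to the
packaged eight-row hazard-ratio table reproduces seven printed p-values
exactly at two decimals; the maternal-grandmother/female cell comes out
0.23 against a printed 0.22, attributable to the printed inputs being
rounded to two decimals while the original authors computed from unrounded
estimates.  The meaningful invariance of the reconstruction is under
raising the estimate and both bounds to a common power (p depends on the
inputs only through ln(est)/(ln CI⁺ − ln CI⁻)); multiplicative rescaling is
*not* an invariance, because the null value 1 does not move.

## Monte-Carlo experiments

All experiments draw from one master seed through `SeedSequence.spawn`
(independent streams for truth draws and evidence draws) and are
bit-reproducible.

**Collider.**  The estimand is the association of θ_f with the other
test's statistic X_m conditional on its own statistic X_f.  The estimator
stratifies X_f into windows of half-width 0.25 on the z scale (the
argument is per-stratum, so stratification rather than a regression
coefficient is primary), contrasts E[X_m | θ_f=1] − E[X_m | θ_f=0] within
each stratum containing at least five replicates of each arm, and pools
strata by inverse variance; a linear partial correlation is reported as a
robustness line.  Predicted signs: positive when only prior association is
present (path through θ_m), negative when only residual correlation is
present (the conditioned-on collider X_f opens the path with reversed
sign), null when both are absent.  In acceptance testing the two signed
regimes are checked per seed at |z| > 3 over ten seeds; the null regime,
having no sign to be stable, is checked as |pooled z| ≤ 3 across the ten
seeds.

**Selection ("data fishing").**  With K = 2, the rule S reports the test
with the larger marginal posterior (exact ties, a measure-zero event, go to
test f).  Because S is a deterministic function of the data, θ ⊥ S | X:
the reported posterior is the unadjusted posterior — the same function
call, which the suite asserts structurally — and calibration holds bin by
bin among selected tests.  The frequentist counterpart conditions on
"test f is null and selected": its two-sided p-value is compared to
Uniform(0,1) by a Kolmogorov–Smirnov test, with the asymptotic 0.01-level
critical value √(−ln(0.005)/2)/√n.

**Operating characteristics.**  Truth θ is drawn from the scenario prior
(or forced all-null while the analyst's prior keeps its stated π — the
classic stress case), evidence follows the model, and FWER / mean power /
FDR are tabulated with Monte-Carlo standard errors for the posterior
threshold rule against unadjusted, Bonferroni, Holm and Benjamini–Hochberg
testing.

Default scenario parameters (π = 0.5, μ = 2, N = 10^5, window 0.25) are the
study conditions throughout; acceptance-level experiments use
N = 10^6 (forward-simulation oracle), 2×10^5 × 10 seeds (collider), 10^5
(selection), 10^4 (shrinkage), and the unit-test suite uses smaller
replicates of the same designs.

## Effect estimation

For continuous effects (log hazard ratios), θ ~ N(m₀, T), x | θ ~ N(θ, S)
gives the conjugate posterior mean m₀ + T(T+S)⁻¹(x − m₀) and covariance
T − T(T+S)⁻¹T; the weight matrix T(T+S)⁻¹ is exposed directly because its
off-diagonal entries *are* the multiplicity adjustment — the weight each
test's estimate receives in its neighbor's posterior.  S is meant to be
assembled from published standard errors (e.g. via the CI reconstruction
above); the normal approximation on the log-ratio scale replaces refitting
survival models whose raw data are unavailable.  The posterior point
estimate is the mean (equal to the mode for Gaussians).  T's correlation is
an elicited input with no endorsed default.

## What the simulations do and do not show

The generator draws exactly from the model the posterior assumes, so
calibration results demonstrate internal coherence — a posterior computed
under the true generative law is calibrated, selection or not — rather than
robustness.  Real summary statistics have estimated variances (t-like
tails), non-Gaussian dependence, and effect sizes that vary by test; none
of that is emulated.  The collider and selection phenomena, however, are
qualitative and survive such misspecification in direction if not in
magnitude.

## Numerical notes and edge cases

* All posterior accumulation is in log space; a configuration with zero
  prior mass contributes −∞ and an all-zero unnormalized posterior raises.
* `single_test_posterior` is a logistic of the log odds — exact at the
  symmetric point and monotone; dogmatic priors (π ∈ {0,1}) short-circuit.
* Degenerate margins make indicator correlation undefined and raise.
* p-scale draws are clipped away from 0 to respect the open-interval
  domain (Beta(0.1, 1) mass near zero is extreme).
* The collider estimator raises when no stratum holds five replicates of
  each arm, suggesting a wider window or larger N.
* CI levels are rejected within 1e−9 of 1, where the implied SE collapses.
* Pairwise-prior construction clips P(1,1) into the Fréchet interval only
  after verifying it lies within 1e−12 of it.

## Scope

Raw survival data, refitting of the original cohort models, sequential /
optional-stopping designs, publication-bias modeling, FDR-controlling
posterior decision rules, and spike-and-slab mixtures of indicators with
continuous effects are out of scope.
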