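# bayesmt — Bayesian multiple testing with correlated hypotheses

When a study reports many hypothesis tests — eight strata of a cohort, a
table of subgroup hazard ratios — should each p-value be "adjusted for
multiplicity", and for how many tests?  The frequentist answer depends on
an arbitrary choice of test family.  `bayesmt` implements the Bayesian
alternative: put a joint prior on the binary hypothesis indicators
θ ∈ {0,1}^K (θ_j = 1 when the alternative holds for test j), a sampling
model p(X | θ) for the observed statistics, and base every decision on the
exact posterior

    p(θ | X) ∝ p(X | θ) p(θ),         p(θ_j = 1 | X) = Σ_{θ: θ_j=1} p(θ | X),

computed by full enumeration over the 2^K configurations (K ≤ 20, log-space
accumulation).  Two structural theorems do the conceptual work:

* **Independent tests need no adjustment.**  If p(θ) factorizes and the
  statistics are conditionally independent given θ, then
  p(θ_j = 1 | X) = p(θ_j = 1 | X_j) exactly — the other tests' data drop
  out of the marginalization.
* **Dependent tests adjust themselves.**  Any prior association between
  indicators, or residual correlation between statistics (the same
  subjects analyzed repeatedly), makes the marginal posterior for one test
  depend on all the data — by the same Bayes' theorem, with no family-size
  bookkeeping.

The package is aimed at biostatisticians and epidemiologists who want to
reason quantitatively about multiplicity: it also ships the frequentist
contrast class (Bonferroni with family-size override, Holm,
Benjamini–Hochberg), post-hoc Wald p-value reconstruction from published
ratio/CI tables, seeded Monte-Carlo experiments for the collider and
data-fishing phenomena, and conjugate Gaussian shrinkage for correlated
continuous effects.

## Worked example

Eight published hazard ratios (four grandparent types × grandchild sex)
with 95% CIs, p-values reconstructed from the printed numbers:

```python
from bayesmt import bygren_ratio_estimates, reconstruct_table, bonferroni

table = reconstruct_table(bygren_ratio_estimates())
print(table[["label", "estimate", "p_2dp"]].to_string(index=False))
```

```
                      label  estimate  p_2dp
  paternal_grandfather/male      0.87   0.67
paternal_grandfather/female      0.91   0.81
  paternal_grandmother/male      0.64   0.21
paternal_grandmother/female      2.69   0.04
  maternal_grandfather/male      1.26   0.46
maternal_grandfather/female      1.32   0.51
  maternal_grandmother/male      0.69   0.28
maternal_grandmother/female      0.56   0.23
```

Each p-value comes from SE = (ln CI⁺ − ln CI⁻)/(2·1.959964) and
z = ln(HR)/SE; seven of the eight match the published column exactly at two
decimals and the eighth differs by one rounding unit (the printed inputs
are themselves rounded).  The one significant cell does not survive the
24-test family a critic proposed — `bonferroni([0.0397], m=24)` gives an
adjusted p of 0.95 — while the Bayesian analysis asks instead how strongly
the eight hypotheses are associated a priori:

```python
from bayesmt import CommonCauseExchangeablePrior, EvidenceModel, EvidenceVector, joint_posterior

prior = CommonCauseExchangeablePrior(pi=0.5, rho=0.5, K=2)   # associated hypotheses
model = EvidenceModel(K=2, mu=2.0)                           # z-scale evidence
res = joint_posterior(prior, model, EvidenceVector([2.0, 2.0]))
print(res.marginal_alt)   # [0.9428 0.9428]  vs 0.8808 when rho=0
```

A concordant neighboring test raises the posterior from 0.881 to 0.943 at
ρ = 0.5; a discordant one (z = −1) lowers it to 0.344 at ρ = 0.9.  The
`examples/` directory holds one narrative script per capability, including
the collider sign reversal under residual dependence and the demonstration
that posterior calibration survives report-the-best selection while
selected null p-values become non-uniform.

## Command line

A thin CLI wraps the library:

```
bayesmt posthoc-p --in table.csv --out pvalues.csv
bayesmt posterior --evidence evidence.csv --config config.yaml --out posteriors.csv
bayesmt adjust --method bonferroni --m 24 --in pvalues.csv --out adjusted.csv
bayesmt simulate collider --spec scenario.yaml --out results/
bayesmt estimate --in effects.csv --config config.yaml --out shrunk.csv
bayesmt fixtures dump --out fixtures/
```

Configs are YAML (`prior:`, `evidence:`, `scenario:` blocks); all tables
are comma-separated UTF-8 with a header row, and every stochastic command
logs its master seed.

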