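"""Selective reporting: poison for p-values, harmless to posteriors.

A researcher runs two tests and reports only the one with the larger
posterior probability of an effect.  Because the selection rule is a
function of the data, the posterior of the selected test is exactly the
posterior computed with no reference to selection — and it stays
calibrated.  The frequentist story differs: among replicates where the
selected test is truly null, its p-value is far from Uniform(0,1).
"""

from bayesmt import ScenarioSpec, run_selection_sim

spec = ScenarioSpec(K=2, pi=0.5, rho=0.0, mu=2.0, N=100_000, seed=7)
res = run_selection_sim(spec)

print("calibration of the selected test's posterior (no selection adjustment):")
print(res.calibration.round(4).to_string(index=False))
print(f"\nselected-and-null p-values: KS distance from uniform = "
      f"{res.ks_statistic:.4f} over n={res.n_selected_null} replicates")
print(f"0.01-level KS critical value: {res.ks_critical_001:.4f} -> "
      f"{'NOT uniform' if res.ks_statistic > res.ks_critical_001 else 'uniform'}")
# Per bin, the empirical frequency of a true effect matches the mean
# posterior within Monte-Carlo error, even though every row was cherry-picked.
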