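"""Monte-Carlo experiments: collider, selection, operating characteristics."""

from dataclasses import replace

import numpy as np
import pytest

from bayesmt import (
    CommonCauseExchangeablePrior,
    ScenarioSpec,
    draw_truths,
    generate_dataset,
    marginal_posterior_batch,
    run_collider_sim,
    run_operating_characteristics,
    run_selection_sim,
)
from bayesmt.evidence import simulate_evidence_matrix
from bayesmt.simulators import _spawn


BASE = ScenarioSpec(K=2, pi=0.5, rho=0.0, mu=2.0, residual_corr=0.0, N=50_000, seed=3)


class TestScenarioSpec:
    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(N=0)
        with pytest.raises(ValueError):
            ScenarioSpec(window=0.0)

    def test_prior_and_model_builders(self):
        spec = replace(BASE, rho=0.4, residual_corr=0.3)
        assert spec.prior().rho == 0.4
        R = spec.model().residual_correlation
        assert R[0, 1] == 0.3 and R[0, 0] == 1.0


class TestCollider:
    def test_prior_association_path_is_positive(self):
        res = run_collider_sim(replace(BASE, rho=0.5))
        assert res.stratified_diff > 3 * res.stratified_se

    def test_residual_collider_path_is_negative(self):
        res = run_collider_sim(replace(BASE, residual_corr=0.8))
        assert res.stratified_diff < -3 * res.stratified_se
        assert res.partial_corr < 0

    def test_no_paths_no_association(self):
        res = run_collider_sim(BASE)
        assert abs(res.stratified_diff) <= 3 * res.stratified_se

    def test_bit_reproducible(self):
        a = run_collider_sim(replace(BASE, rho=0.5, N=20_000))
        b = run_collider_sim(replace(BASE, rho=0.5, N=20_000))
        assert a.stratified_diff == b.stratified_diff
        assert a.partial_corr == b.partial_corr

    def test_empty_strata_error(self):
        # almost no alternative draws: strata can't hold 5 of each arm
        with pytest.raises(ValueError, match="stratum"):
            run_collider_sim(replace(BASE, pi=1e-4, N=200))

    def test_requires_two_tests(self):
        with pytest.raises(ValueError, match="K=2"):
            run_collider_sim(replace(BASE, K=3))


class TestSelection:
    def test_calibration_under_selection(self):
        res = run_selection_sim(replace(BASE, N=100_000))
        big = res.calibration[res.calibration["n"] >= 200]
        assert len(big) >= 5
        err = (big["freq_alt"] - big["mean_posterior"]).abs()
        assert (err <= 3 * big["binom_se"]).all()

    def test_selected_null_pvalues_not_uniform(self):
        res = run_selection_sim(replace(BASE, N=100_000))
        assert res.ks_statistic > res.ks_critical_001

    def test_selection_uses_the_unadjusted_posterior(self):
        # S is a function of the data; the reported value for the selected
        # test is the plain marginal posterior, recomputable ignoring S
        spec = replace(BASE, N=5_000)
        res = run_selection_sim(spec)
        rng_theta, rng_x = _spawn(spec.seed, 2)
        thetas = draw_truths(spec.prior(), spec.N, rng_theta)
        X = simulate_evidence_matrix(spec.model(), thetas, rng_x)
        marg = marginal_posterior_batch(spec.prior(), spec.model(), X)
        S = (marg[:, 1] > marg[:, 0]).astype(int)
        q = marg[np.arange(spec.N), S]
        # the calibration table was built from exactly these values
        assert res.calibration["n"].sum() == spec.N
        assert res.calibration["mean_posterior"].min() >= q.min() - 1e-12

    def test_degenerate_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            try:
                run_selection_sim(replace(BASE, N=1))
            except ValueError:
                pass  # a single replicate may leave the selected-null set empty


class TestOperatingCharacteristics:
    def test_single_test_fwer_is_the_level(self):
        spec = ScenarioSpec(K=1, pi=0.5, mu=2.0, N=40_000, seed=5)
        tab = run_operating_characteristics(spec, truth_all_null=True)
        row = tab.set_index("method").loc["unadjusted"]
        assert row["fwer"] == pytest.approx(0.05, abs=3 * row["fwer_se"] + 1e-9)

    def test_all_null_family_of_eight(self):
        spec = ScenarioSpec(K=8, pi=0.5, mu=2.0, N=20_000, seed=6)
        tab = run_operating_characteristics(spec, truth_all_null=True).set_index("method")
        una = tab.loc["unadjusted"]
        assert una["fwer"] == pytest.approx(1 - 0.95**8, abs=3 * una["fwer_se"])
        bon = tab.loc["bonferroni"]
        assert bon["fwer"] <= 0.05 + 3 * bon["fwer_se"]
        # Holm never rejects less than Bonferroni
        assert tab.loc["holm", "fwer"] >= bon["fwer"] - 1e-12

    def test_mixed_truth_reports_power(self):
        spec = ScenarioSpec(K=4, pi=0.5, rho=0.3, mu=2.5, N=5_000, seed=7)
        tab = run_operating_characteristics(spec).set_index("method")
        assert 0.0 < tab.loc["posterior_tau", "power"] <= 1.0
        assert tab.loc["unadjusted", "power"] >= tab.loc["bonferroni", "power"] - 1e-12


class TestGenerateDataset:
    def test_byte_identical_repeats(self, tmp_path):
        spec = replace(BASE, K=4, N=1)
        p1 = tmp_path / "e1.csv", tmp_path / "t1.csv"
        p2 = tmp_path / "e2.csv", tmp_path / "t2.csv"
        generate_dataset(spec, 42, *p1)
        generate_dataset(spec, 42, *p2)
        assert p1[0].read_bytes() == p2[0].read_bytes()
        assert p1[1].read_bytes() == p2[1].read_bytes()

    def test_all_null_truth(self, tmp_path):
        spec = ScenarioSpec(K=8, pi=0.0, seed=1)
        _, truth = generate_dataset(spec, 9, tmp_path / "e.csv", tmp_path / "t.csv")
        vals = [int(line.split(",")[1]) for line in truth.read_text().splitlines()[1:]]
        assert vals == [0] * 8

    def test_perfect_association_gives_concordant_truths(self, rng):
        prior = CommonCauseExchangeablePrior(pi=0.5, rho=1.0, K=2)
        thetas = draw_truths(prior, 10_000, rng)
        assert np.all(thetas[:, 0] == thetas[:, 1])
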