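"""Exact enumeration posteriors: closed forms, reductions, MC agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bayesmt import (
    CommonCauseExchangeablePrior,
    EvidenceModel,
    EvidenceVector,
    IndependentPrior,
    decide,
    joint_posterior,
    loglik,
    marginal_posterior,
    marginal_posterior_batch,
    single_test_posterior,
)
from bayesmt.simulators import ScenarioSpec, draw_truths
from bayesmt.evidence import simulate_evidence_matrix

PHI = stats.norm.pdf


class TestClosedForms:
    def test_independent_prior_matches_per_test_bayes(self):
        # phi(0) / (phi(0) + phi(2)) per coordinate
        res = joint_posterior(
            IndependentPrior([0.5, 0.5]),
            EvidenceModel(K=2, mu=2.0),
            EvidenceVector([2.0, 2.0]),
        )
        want = PHI(0) / (PHI(0) + PHI(2))
        assert res.marginal_alt == pytest.approx([want, want], abs=1e-10)
        assert want == pytest.approx(0.8808, abs=5e-5)

    def test_perfect_prior_association_pools_the_evidence(self):
        # rho=1 collapses to one pooled hypothesis: phi(0)^2/(phi(0)^2+phi(2)^2)
        res = joint_posterior(
            CommonCauseExchangeablePrior(pi=0.5, rho=1.0, K=2),
            EvidenceModel(K=2, mu=2.0),
            EvidenceVector([2.0, 2.0]),
        )
        want = PHI(0) ** 2 / (PHI(0) ** 2 + PHI(2) ** 2)
        assert res.marginal_alt == pytest.approx([want, want], abs=1e-10)
        assert want == pytest.approx(0.9820, abs=5e-5)

    def test_flat_likelihood_returns_the_prior(self):
        prior = CommonCauseExchangeablePrior(pi=0.3, rho=0.6, K=2)
        res = joint_posterior(
            prior, EvidenceModel(K=2, mu=0.0), EvidenceVector([1.3, -0.2])
        )
        for cfg, mass in prior.table().items():
            assert res.joint[cfg] == pytest.approx(mass, abs=1e-10)

    def test_joint_sums_to_one_and_marginals_consistent(self):
        res = joint_posterior(
            CommonCauseExchangeablePrior(pi=0.4, rho=0.7, K=3),
            EvidenceModel(K=3, mu=2.0),
            EvidenceVector([1.0, -0.5, 2.5]),
        )
        assert math.fsum(res.joint.values()) == pytest.approx(1.0, abs=1e-10)
        for j in range(3):
            marg = sum(v for cfg, v in res.joint.items() if cfg[j] == 1)
            assert res.marginal_alt[j] == pytest.approx(marg, abs=1e-10)


class TestSingleTestPosterior:
    def test_uninformative_datum(self):
        assert single_test_posterior(0.5, -1.3, -1.3) == 0.5

    def test_density_ratio_arithmetic(self):
        got = single_test_posterior(
            0.5, float(stats.norm.logpdf(2.0)), float(stats.norm.logpdf(0.0))
        )
        assert got == pytest.approx(0.8808, abs=5e-5)

    def test_dogmatic_priors(self):
        assert single_test_posterior(0.0, 0.0, 100.0) == 0.0
        assert single_test_posterior(1.0, 100.0, 0.0) == 1.0


class TestIndependenceReduction:
    """With independent prior and identity residual correlation, other tests'
    data are irrelevant: the marginal equals the single-test posterior."""

    @given(
        pi=st.floats(0.05, 0.95),
        mu=st.floats(0.5, 4.0),
        x0=st.floats(-3, 4),
        x1=st.floats(-3, 4),
        x1_perturbed=st.floats(-3, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_reduction_and_invariance(self, pi, mu, x0, x1, x1_perturbed):
        prior = IndependentPrior([pi, pi])
        model = EvidenceModel(K=2, mu=mu)
        m_a = marginal_posterior(prior, model, EvidenceVector([x0, x1]), 0)
        m_b = marginal_posterior(prior, model, EvidenceVector([x0, x1_perturbed]), 0)
        single = single_test_posterior(
            pi,
            float(stats.norm.logpdf(x0)),
            float(stats.norm.logpdf(x0 - mu)),
        )
        assert m_a == single  # bit-identical reduction
        assert m_a == m_b  # other test's data are irrelevant
        # full enumeration agrees with the reduction to numerical precision
        enum = joint_posterior(prior, model, EvidenceVector([x0, x1])).marginal_alt[0]
        assert enum == pytest.approx(single, abs=1e-12)

    def test_dependent_prior_breaks_invariance(self):
        # with a priori association, the other test's data genuinely matter
        model = EvidenceModel(K=2, mu=2.0)
        x = EvidenceVector([2.5, 2.5])
        dep = marginal_posterior(
            CommonCauseExchangeablePrior(pi=0.5, rho=0.9, K=2), model, x, 0
        )
        indep = marginal_posterior(
            CommonCauseExchangeablePrior(pi=0.5, rho=0.0, K=2), model, x, 0
        )
        assert dep > indep

    def test_residual_dependence_breaks_invariance(self):
        R = np.array([[1.0, 0.7], [0.7, 1.0]])
        model = EvidenceModel(K=2, mu=2.0, residual_correlation=R)
        prior = IndependentPrior([0.5, 0.5])
        a = marginal_posterior(prior, model, EvidenceVector([2.0, 0.0]), 0)
        b = marginal_posterior(prior, model, EvidenceVector([2.0, 3.0]), 0)
        assert a != pytest.approx(b, abs=1e-6)


class TestDecide:
    def test_threshold_is_strict(self):
        res = joint_posterior(
            IndependentPrior([0.5]), EvidenceModel(K=1, mu=0.0), EvidenceVector([1.0])
        )
        assert res.marginal_alt[0] == pytest.approx(0.5, abs=1e-12)
        assert not decide(res, tau=0.5)[0]  # boundary retains the null

    def test_decisions_follow_marginals(self):
        res = joint_posterior(
            IndependentPrior([0.5, 0.5]),
            EvidenceModel(K=2, mu=2.0),
            EvidenceVector([2.0, -2.0]),
        )
        assert decide(res, tau=0.5).tolist() == [True, False]

    def test_tau_domain(self):
        res = joint_posterior(
            IndependentPrior([0.5]), EvidenceModel(K=1), EvidenceVector([0.0])
        )
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                decide(res, tau=bad)


def test_index_out_of_range():
    with pytest.raises(IndexError):
        marginal_posterior(
            IndependentPrior([0.5, 0.5]),
            EvidenceModel(K=2),
            EvidenceVector([0.0, 0.0]),
            2,
        )


def test_rho_one_symmetry():
    prior = CommonCauseExchangeablePrior(pi=0.4, rho=1.0, K=4)
    res = joint_posterior(
        prior, EvidenceModel(K=4, mu=2.0), EvidenceVector([1.0, 2.0, -0.5, 0.3])
    )
    assert np.ptp(res.marginal_alt) < 1e-10


class TestBatchAgreesWithEnumeration:
    @pytest.mark.parametrize("residual", [0.0, 0.6])
    def test_z_scale(self, rng, residual):
        R = None
        if residual:
            R = np.array([[1.0, residual], [residual, 1.0]])
        prior = CommonCauseExchangeablePrior(pi=0.3, rho=0.5, K=2)
        model = EvidenceModel(K=2, mu=2.0, residual_correlation=R)
        X = rng.normal(size=(20, 2))
        batch = marginal_posterior_batch(prior, model, X)
        for i, row in enumerate(X):
            res = joint_posterior(prior, model, EvidenceVector(row))
            assert batch[i] == pytest.approx(res.marginal_alt, abs=1e-10)

    def test_p_scale(self, rng):
        prior = IndependentPrior([0.4, 0.6])
        model = EvidenceModel(K=2, scale="p", a=0.1)
        X = rng.uniform(0.01, 1.0, size=(20, 2))
        batch = marginal_posterior_batch(prior, model, X)
        for i, row in enumerate(X):
            res = joint_posterior(prior, model, EvidenceVector(row, scale="p"))
            assert batch[i] == pytest.approx(res.marginal_alt, abs=1e-10)


def test_monte_carlo_oracle_single_setting():
    """Windowed forward simulation reproduces the enumeration posterior."""
    spec = ScenarioSpec(K=2, pi=0.4, rho=0.6, mu=2.0, residual_corr=0.3, N=300_000, seed=11)
    prior, model = spec.prior(), spec.model()
    rng = np.random.default_rng(spec.seed)
    thetas = draw_truths(prior, spec.N, rng)
    X = simulate_evidence_matrix(model, thetas, rng)
    x_obs = np.array([1.5, 0.5])
    w = 0.25
    sel = np.all(np.abs(X - x_obs) <= w, axis=1)
    n = int(sel.sum())
    assert n > 500
    emp = thetas[sel, 0].mean()
    model_avg = marginal_posterior_batch(prior, model, X[sel]).mean(axis=0)[0]
    se = math.sqrt(max(model_avg * (1 - model_avg), 1e-12) / n)
    assert abs(emp - model_avg) <= 3 * se
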