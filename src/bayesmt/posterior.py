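"""Exact joint and marginal posteriors over hypothesis configurations.

The posterior over theta in {0,1}^K is computed by full enumeration,

    p(theta | X)  propto  p(X | theta) p(theta),

normalized over all 2^K configurations.  The per-test marginal alternative
probability p(theta_j = 1 | X) sums the joint mass over configurations with
bit j set.  All accumulation is in log space via log-sum-exp; exactness (up
to floating point) rather than approximation is the design goal, hence the
K <= 20 enumeration cap.

Two structural facts about this posterior carry the substance of the method:

* if the prior factorizes over tests and the statistics are conditionally
  independent given theta, the marginal posterior for test j collapses to the
  single-test posterior p(theta_j = 1 | X_j) — data from other tests are
  irrelevant, so no adjustment across independent tests is needed;
* if either the prior or the residual correlation couples tests, the
  marginal posterior for test j genuinely depends on the other tests' data —
  the adjustment is then automatic, carried by Bayes' theorem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.special import logsumexp

from .evidence import EvidenceModel, EvidenceVector, loglik
from .priors import JointPrior, all_configs

__all__ = [
    "PosteriorResult",
    "joint_posterior",
    "marginal_posterior",
    "marginal_posterior_batch",
    "single_test_posterior",
    "decide",
]


@dataclass
class PosteriorResult:
    """Normalized joint posterior table plus the K marginal probabilities."""

    joint: Dict[Tuple[int, ...], float]
    marginal_alt: np.ndarray
    log_normalizer: float

    @property
    def K(self) -> int:
        return len(self.marginal_alt)


def joint_posterior(
    prior: JointPrior, model: EvidenceModel, x: EvidenceVector
) -> PosteriorResult:
    """Enumerate p(theta | x) over all 2^K configurations."""
    K = prior.K
    if model.K != K or x.K != K:
        raise ValueError(
            f"dimension mismatch: prior K={K}, model K={model.K}, x K={x.K}"
        )
    configs = list(all_configs(K))
    logw = np.full(len(configs), -np.inf)
    for idx, cfg in enumerate(configs):
        pm = prior.mass(cfg)
        if pm > 0.0:
            logw[idx] = np.log(pm) + loglik(model, x, cfg)
    if not np.any(np.isfinite(logw)):
        raise ValueError("all configurations have zero unnormalized posterior mass")
    log_norm = float(logsumexp(logw))
    post = np.exp(logw - log_norm)
    post /= post.sum()  # tidy rounding; already ~1
    joint = dict(zip(configs, post.tolist()))
    marg = np.zeros(K)
    for cfg, w in zip(configs, post):
        for j, b in enumerate(cfg):
            if b:
                marg[j] += w
    return PosteriorResult(joint=joint, marginal_alt=marg, log_normalizer=log_norm)


def marginal_posterior(
    prior: JointPrior, model: EvidenceModel, x: EvidenceVector, j: int
) -> float:
    """p(theta_j = 1 | x), marginalizing the joint posterior over the rest.

    When the prior factorizes over tests and the statistics are conditionally
    independent given theta, the marginalization collapses exactly to the
    single-test posterior p(theta_j = 1 | x_j); that reduction is applied
    here, so in the fully independent case the result is bit-identical to
    ``single_test_posterior`` and provably invariant to the other tests'
    data.  (Full enumeration agrees with the reduction to within rounding;
    the test suite checks both.)
    """
    from .priors import IndependentPrior

    if not 0 <= j < prior.K:
        raise IndexError(f"test index {j} out of range for K={prior.K}")
    if isinstance(prior, IndependentPrior) and not model.has_residual_dependence:
        x_j = EvidenceVector([x.to_z().values[j]] if model.scale == "z"
                             else [x.values[j]], scale=model.scale)
        sub = EvidenceModel(
            K=1,
            scale=model.scale,
            mu=None if model.mu is None else model.mu[j],
            a=None if model.a is None else model.a[j],
        )
        f0 = loglik(sub, x_j, (0,))
        f1 = loglik(sub, x_j, (1,))
        return single_test_posterior(prior.pi[j], f0, f1)
    return float(joint_posterior(prior, model, x).marginal_alt[j])


def marginal_posterior_batch(
    prior: JointPrior, model: EvidenceModel, X: np.ndarray
) -> np.ndarray:
    """Marginal alternative probabilities for many evidence rows at once.

    ``X`` has shape (n, K) on the model's scale.  Returns an (n, K) array of
    p(theta_j = 1 | X_i).  This is the same enumeration as
    ``joint_posterior`` vectorized over rows; the Monte-Carlo simulators
    depend on it for throughput.
    """
    from scipy import stats  # local to keep module import light

    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != prior.K:
        raise ValueError(f"X must have shape (n, {prior.K}), got {X.shape}")
    if model.K != prior.K:
        raise ValueError("prior and model dimensions differ")
    K = prior.K
    configs = list(all_configs(K))
    n = X.shape[0]
    logw = np.full((n, len(configs)), -np.inf)

    if model.scale == "p":
        l1 = np.log(model.a) + (model.a - 1.0) * np.log(X)  # (n, K)
        l0 = np.zeros_like(X)
    elif model.residual_correlation is None:
        l0 = stats.norm.logpdf(X)
        l1 = stats.norm.logpdf(X - model.mu)
    else:
        l0 = l1 = None  # full MVN per configuration below

    for idx, cfg in enumerate(configs):
        pm = prior.mass(cfg)
        if pm <= 0.0:
            continue
        bits = np.asarray(cfg, dtype=bool)
        if l0 is not None:
            ll = np.where(bits[None, :], l1, l0).sum(axis=1)
        else:
            mean = model.mu * bits
            ll = stats.multivariate_normal.logpdf(
                X, mean=mean, cov=model.residual_correlation
            )
        logw[:, idx] = np.log(pm) + ll

    log_norm = logsumexp(logw, axis=1, keepdims=True)
    post = np.exp(logw - log_norm)
    marg = np.zeros((n, K))
    for idx, cfg in enumerate(configs):
        for j, b in enumerate(cfg):
            if b:
                marg[:, j] += post[:, idx]
    return marg


def single_test_posterior(pi: float, f0_loglik: float, f1_loglik: float) -> float:
    """Posterior alternative probability for one test in isolation.

    pi * exp(f1) / (pi * exp(f1) + (1 - pi) * exp(f0)), evaluated stably in
    log space.  ``f0_loglik`` and ``f1_loglik`` are the null and alternative
    log densities at the observed statistic.
    """
    pi = float(pi)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi={pi} outside [0, 1]")
    if pi == 0.0:
        return 0.0
    if pi == 1.0:
        return 1.0
    from scipy.special import expit

    # logistic form: exact at the symmetric point and monotone in the log odds
    log_odds = (np.log(pi) - np.log1p(-pi)) + (f1_loglik - f0_loglik)
    return float(expit(log_odds))


def decide(result: PosteriorResult, tau: float = 0.5) -> np.ndarray:
    """Accept the alternative for test j iff p(theta_j=1 | X) > tau (strict).

    Boundary ties retain the null.  The default tau = 0.5 accepts the
    alternative exactly when it is more probable than the null a posteriori.
    """
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau={tau} outside (0, 1)")
    return result.marginal_alt > tau
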