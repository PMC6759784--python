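"""Conjugate Gaussian shrinkage for correlated continuous effects.

For effect estimation the binary indicators are replaced by continuous
effects theta (e.g. log hazard ratios).  With a Gaussian prior
theta ~ N(m0, T), Gaussian estimates x | theta ~ N(theta, S), the posterior
is Gaussian with

    mean = m0 + T (T + S)^{-1} (x - m0),
    cov  = T - T (T + S)^{-1} T.

Off-diagonal structure in T lets each test's estimate borrow strength from
the others — the continuous analog of prior association between hypothesis
indicators.  When T is diagonal each coordinate shrinks toward its own prior
mean independently; no cross-learning occurs without prior correlation.

S is typically assembled from published standard errors (see
``posthoc.se_from_ci`` for CIs on the ratio scale); working on the log-ratio
scale with a normal approximation replaces refitting the original survival
models, whose raw data are usually unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["GaussianEffectModel", "conjugate_posterior", "shrinkage_report"]


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    eig = np.linalg.eigvalsh(M)
    if eig.min() < -1e-10 * max(1.0, abs(eig.max())):
        raise ValueError(f"{name} is not positive semidefinite (min eig {eig.min():.3g})")
    return M


@dataclass
class GaussianEffectModel:
    """Gaussian prior N(prior_mean, T) and sampling model N(theta, S)."""

    prior_mean: np.ndarray
    prior_cov: np.ndarray
    sampling_cov: np.ndarray

    def __post_init__(self):
        self.prior_cov = _check_psd(self.prior_cov, "prior covariance T")
        self.sampling_cov = _check_psd(self.sampling_cov, "sampling covariance S")
        K = self.prior_cov.shape[0]
        if self.sampling_cov.shape[0] != K:
            raise ValueError("T and S dimensions differ")
        self.prior_mean = np.broadcast_to(
            np.asarray(self.prior_mean, float), (K,)
        ).copy()
        total = self.prior_cov + self.sampling_cov
        try:
            np.linalg.cholesky(total)
        except np.linalg.LinAlgError as exc:
            raise ValueError("T + S is singular; posterior undefined") from exc

    @property
    def K(self) -> int:
        return self.prior_cov.shape[0]


def _gain(model: GaussianEffectModel) -> np.ndarray:
    # T (T+S)^{-1} via a solve on the transpose; symmetric T keeps this exact
    total = model.prior_cov + model.sampling_cov
    return np.linalg.solve(total, model.prior_cov).T


def conjugate_posterior(
    model: GaussianEffectModel, x: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior mean vector and covariance of theta given estimates x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.K,):
        raise ValueError(f"x must have shape ({model.K},), got {x.shape}")
    W = _gain(model)
    mean = model.prior_mean + W @ (x - model.prior_mean)
    cov = model.prior_cov - W @ model.prior_cov
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def shrinkage_report(model: GaussianEffectModel, x: np.ndarray) -> np.ndarray:
    """The weight matrix T (T + S)^{-1}.

    Row j gives the weight of each observation in the posterior mean of
    effect j (relative to the prior mean); off-diagonal entries quantify
    cross-test borrowing of strength.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.K,):
        raise ValueError(f"x must have shape ({model.K},), got {x.shape}")
    return _gain(model)
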