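"""Sampling models p(X | theta) for the observed per-test statistics.

Each test j reports one statistic X_j; given the indicator theta_j the
statistic is drawn from a null or an alternative density.  Two scales are
supported:

z scale
    X_j ~ N(0, 1) under the null, N(mu_j, 1) under the alternative
    (shift-only alternative, default mu_j = 2).  Residual dependence of the
    statistics *given* theta — e.g. the same subjects analyzed several times —
    is expressed through a correlation matrix R: jointly X ~ MVN(mu * theta, R).

p scale
    X_j ~ Uniform(0, 1) under the null, Beta(a_j, 1) under the alternative
    (density a x^(a-1), mass near zero; default a_j = 0.1).  Residual
    dependence is deliberately not supported on this scale; combining the two
    raises instead of silently approximating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .priors import _as_config

__all__ = [
    "EvidenceVector",
    "EvidenceModel",
    "loglik",
    "simulate_evidence",
    "p_to_z",
    "z_to_p",
]


@dataclass(frozen=True)
class EvidenceVector:
    """K observed statistics on one common scale.

    ``scale`` is "z", "p" or "log_ratio_with_se"; the latter carries per-test
    standard errors and is converted to the z scale by ``to_z()``.
    """

    values: Tuple[float, ...]
    scale: str = "z"
    se: Optional[Tuple[float, ...]] = None

    def __init__(self, values, scale: str = "z", se=None):
        vals = tuple(float(v) for v in np.atleast_1d(np.asarray(values, float)))
        if scale not in ("z", "p", "log_ratio_with_se"):
            raise ValueError(f"unknown scale {scale!r}")
        if scale == "p":
            for v in vals:
                if not 0.0 < v <= 1.0:
                    raise ValueError(f"p-scale value {v} outside (0, 1]")
        if scale == "log_ratio_with_se":
            if se is None:
                raise ValueError("log_ratio_with_se requires standard errors")
            se = tuple(float(s) for s in np.atleast_1d(np.asarray(se, float)))
            if len(se) != len(vals):
                raise ValueError("values and se lengths differ")
            for s in se:
                if not s > 0:
                    raise ValueError(f"standard error {s} must be positive")
        elif se is not None:
            se = tuple(float(s) for s in np.atleast_1d(np.asarray(se, float)))
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "scale", scale)
        object.__setattr__(self, "se", se)

    @property
    def K(self) -> int:
        return len(self.values)

    def to_z(self) -> "EvidenceVector":
        """Convert to the z scale (Wald z for log-ratio inputs)."""
        if self.scale == "z":
            return self
        if self.scale == "log_ratio_with_se":
            z = [v / s for v, s in zip(self.values, self.se)]
            return EvidenceVector(z, scale="z")
        return EvidenceVector([p_to_z(p) for p in self.values], scale="z")


def _check_corr(R: np.ndarray, K: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (K, K):
        raise ValueError(f"residual correlation must be {K}x{K}, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("residual correlation matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("residual correlation matrix must have unit diagonal")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("residual correlation matrix is not positive definite") from exc
    return R


@dataclass
class EvidenceModel:
    """Null/alternative densities per test plus optional residual correlation.

    Parameters
    ----------
    K : number of tests.
    scale : "z" or "p".
    mu : alternative mean shift per test (z scale); scalar broadcasts.
    a : alternative Beta(a, 1) exponent per test (p scale), each in (0, 1).
    residual_correlation : K x K correlation matrix R of the statistics given
        theta; identity (None) means conditionally independent tests.  Only
        valid on the z scale.
    """

    K: int
    scale: str = "z"
    mu: np.ndarray = None
    a: np.ndarray = None
    residual_correlation: Optional[np.ndarray] = None

    def __post_init__(self):
        self.K = int(self.K)
        if self.K < 1:
            raise ValueError("need at least one test")
        if self.scale not in ("z", "p"):
            raise ValueError(f"unknown evidence scale {self.scale!r}")
        if self.scale == "z":
            mu = 2.0 if self.mu is None else self.mu
            self.mu = np.broadcast_to(np.asarray(mu, float), (self.K,)).copy()
            self.a = None
        else:
            a = 0.1 if self.a is None else self.a
            self.a = np.broadcast_to(np.asarray(a, float), (self.K,)).copy()
            if np.any((self.a <= 0) | (self.a >= 1)):
                raise ValueError("alternative p-density exponent a must lie in (0, 1)")
            self.mu = None
            if self.residual_correlation is not None:
                raise ValueError(
                    "residual correlation is only supported on the z scale; "
                    "p-scale margins with dependence are rejected, not approximated"
                )
        if self.residual_correlation is not None:
            R = _check_corr(self.residual_correlation, self.K)
            if np.allclose(R, np.eye(self.K), atol=1e-15):
                R = None
            self.residual_correlation = R

    @property
    def has_residual_dependence(self) -> bool:
        return self.residual_correlation is not None

    def mean_vector(self, config: Sequence[int]) -> np.ndarray:
        bits = np.asarray(_as_config(config), float)
        if bits.size != self.K:
            raise ValueError(f"configuration length {bits.size} != K={self.K}")
        return self.mu * bits


def loglik(model: EvidenceModel, x: EvidenceVector, config: Sequence[int]) -> float:
    """log p(x | theta = config) under the evidence model.

    With identity residual correlation this is the sum of per-test log
    densities; with a general R it is a multivariate normal log density with
    mean mu * theta and covariance R.
    """
    bits = _as_config(config)
    if len(bits) != model.K or x.K != model.K:
        raise ValueError(
            f"dimension mismatch: model K={model.K}, x K={x.K}, config K={len(bits)}"
        )
    if model.scale == "p":
        if x.scale != "p":
            raise ValueError("p-scale model requires p-scale evidence")
        out = 0.0
        for a_j, b, v in zip(model.a, bits, x.values):
            out += (a_j - 1.0) * np.log(v) + np.log(a_j) if b else 0.0
        return float(out)
    xv = x.to_z()
    vals = np.asarray(xv.values, float)
    mean = model.mean_vector(bits)
    if model.residual_correlation is None:
        return float(np.sum(stats.norm.logpdf(vals - mean)))
    return float(
        stats.multivariate_normal.logpdf(vals, mean=mean, cov=model.residual_correlation)
    )


def simulate_evidence(
    model: EvidenceModel, config: Sequence[int], rng_seed
) -> EvidenceVector:
    """Draw one evidence vector from p(X | theta = config).

    ``rng_seed`` may be an int seed or a ``numpy.random.Generator``.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    bits = _as_config(config)
    if len(bits) != model.K:
        raise ValueError(f"configuration length {len(bits)} != K={model.K}")
    if model.scale == "p":
        vals = [
            float(rng.beta(a_j, 1.0)) if b else float(rng.uniform())
            for a_j, b in zip(model.a, bits)
        ]
        # guard the open-interval invariant on the p scale
        vals = [min(max(v, 1e-300), 1.0) for v in vals]
        return EvidenceVector(vals, scale="p")
    mean = model.mean_vector(bits)
    if model.residual_correlation is None:
        vals = mean + rng.standard_normal(model.K)
    else:
        vals = rng.multivariate_normal(mean, model.residual_correlation)
    return EvidenceVector(vals, scale="z")


def simulate_evidence_matrix(
    model: EvidenceModel, configs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draws: one evidence row per configuration row (z scale only
    for correlated models).  Used by the Monte-Carlo simulators."""
    configs = np.asarray(configs, float)
    n, K = configs.shape
    if K != model.K:
        raise ValueError(f"configuration width {K} != K={model.K}")
    if model.scale == "p":
        u = rng.uniform(size=(n, K))
        # inverse-CDF for Beta(a,1): F^{-1}(u) = u^(1/a)
        alt = u ** (1.0 / model.a)
        return np.where(configs > 0, alt, u)
    mean = configs * model.mu
    if model.residual_correlation is None:
        return mean + rng.standard_normal((n, K))
    L = np.linalg.cholesky(model.residual_correlation)
    return mean + rng.standard_normal((n, K)) @ L.T


def p_to_z(p: float) -> float:
    """Two-sided p-value to nonnegative z: z = Phi^{-1}(1 - p/2)."""
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    return float(stats.norm.isf(p / 2.0))


def z_to_p(z: float) -> float:
    """z statistic to two-sided p-value: p = 2(1 - Phi(|z|))."""
    return float(2.0 * stats.norm.sf(abs(float(z))))
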