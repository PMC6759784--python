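"""Joint prior distributions over binary hypothesis-indicator vectors.

A multiple-testing problem with K tests is indexed by a vector
theta in {0,1}^K, where theta_j = 1 means the alternative hypothesis holds
for test j and theta_j = 0 means the null holds.  Multiplicity enters the
Bayesian analysis exclusively through the joint prior p(theta): if the prior
factorizes, the tests share no prior information; any a priori association
between the indicators is the channel through which one test's data inform
another test's hypothesis.

Four prior families are provided:

``IndependentPrior``
    Independent Bernoulli(pi_j) indicators; the no-adjustment regime.
``CommonCauseExchangeablePrior``
    A two-component mixture: with probability ``rho`` all indicators copy a
    single shared Bernoulli(pi) draw; otherwise they are i.i.d.
    Bernoulli(pi).  The pairwise correlation of any two indicators is
    exactly ``rho``, and each margin is exactly ``pi``, so the family spans
    independence (rho=0) through a single pooled hypothesis (rho=1).  It
    cannot represent negative association.
``PairwisePrior``
    K=2 with explicit margins (pi_f, pi_m) and Pearson correlation rho of
    either sign; rejected when the implied 2x2 table violates the Frechet
    bounds.
``ExplicitTablePrior``
    An arbitrary probability table over {0,1}^K.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "ENUMERATION_LIMIT",
    "HypothesisConfig",
    "JointPrior",
    "IndependentPrior",
    "CommonCauseExchangeablePrior",
    "PairwisePrior",
    "ExplicitTablePrior",
    "prior_mass",
    "prior_table",
    "pairwise_correlation",
    "all_configs",
]

#: Hard cap on the number of tests for full enumeration (2^20 ~ 1e6 configs).
ENUMERATION_LIMIT = 20

_MASS_TOL = 1e-12


def _as_config(bits: Iterable[int]) -> Tuple[int, ...]:
    out = tuple(int(b) for b in bits)
    if len(out) < 1:
        raise ValueError("a hypothesis configuration needs at least one test")
    for b in out:
        if b not in (0, 1):
            raise ValueError(f"hypothesis indicators must be 0 or 1, got {b}")
    return out


@dataclass(frozen=True)
class HypothesisConfig:
    """An assignment theta in {0,1}^K of null/alternative across K tests."""

    bits: Tuple[int, ...]

    def __init__(self, bits: Iterable[int]):
        object.__setattr__(self, "bits", _as_config(bits))

    @property
    def K(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)

    def __len__(self) -> int:
        return len(self.bits)


def all_configs(K: int) -> Iterable[Tuple[int, ...]]:
    """Iterate over all 2^K configurations in lexicographic order."""
    if K > ENUMERATION_LIMIT:
        raise ValueError(
            f"K={K} exceeds the enumeration limit of {ENUMERATION_LIMIT} tests"
        )
    return itertools.product((0, 1), repeat=K)


class JointPrior:
    """Base class for joint priors over {0,1}^K."""

    K: int

    def mass(self, config: Sequence[int]) -> float:
        raise NotImplementedError

    def _check_dim(self, config: Sequence[int]) -> Tuple[int, ...]:
        bits = _as_config(config)
        if len(bits) != self.K:
            raise ValueError(
                f"configuration has {len(bits)} bits but the prior is over "
                f"{self.K} tests"
            )
        return bits

    def table(self) -> Dict[Tuple[int, ...], float]:
        """Materialize the full probability table over all 2^K configurations."""
        tab = {cfg: self.mass(cfg) for cfg in all_configs(self.K)}
        total = math.fsum(tab.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prior table sums to {total!r}, not 1")
        return tab


@dataclass
class IndependentPrior(JointPrior):
    """Independent Bernoulli indicators with per-test alternative probabilities."""

    pi: Tuple[float, ...]

    def __init__(self, pi: Sequence[float]):
        pi = tuple(float(p) for p in np.atleast_1d(np.asarray(pi, dtype=float)))
        if len(pi) < 1:
            raise ValueError("need at least one test")
        for p in pi:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prior probability {p} outside [0, 1]")
        self.pi = pi

    @property
    def K(self) -> int:
        return len(self.pi)

    def mass(self, config: Sequence[int]) -> float:
        bits = self._check_dim(config)
        out = 1.0
        for p, b in zip(self.pi, bits):
            out *= p if b else (1.0 - p)
        return out


@dataclass
class CommonCauseExchangeablePrior(JointPrior):
    """Exchangeable mixture prior with pairwise indicator correlation rho.

    With probability ``rho`` a single latent Bernoulli(pi) draw is copied to
    every indicator; with probability ``1 - rho`` the indicators are i.i.d.
    Bernoulli(pi).  Margins are exactly pi and corr(theta_i, theta_j) = rho.
    """

    pi: float
    rho: float
    K: int = 2

    def __post_init__(self):
        self.pi = float(self.pi)
        self.rho = float(self.rho)
        self.K = int(self.K)
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi={self.pi} outside [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(
                f"rho={self.rho} outside [0, 1]; negative association requires "
                "ExplicitTablePrior or PairwisePrior"
            )
        if self.K < 1:
            raise ValueError("need at least one test")

    def mass(self, config: Sequence[int]) -> float:
        bits = self._check_dim(config)
        s = sum(bits)
        iid = self.pi**s * (1.0 - self.pi) ** (self.K - s)
        if s == 0:
            shared = 1.0 - self.pi
        elif s == self.K:
            shared = self.pi
        else:
            shared = 0.0
        return self.rho * shared + (1.0 - self.rho) * iid


@dataclass
class PairwisePrior(JointPrior):
    """Two-test prior with explicit margins and correlation of either sign.

    The joint table is determined by the moments:
    P(1,1) = pi_f*pi_m + rho*sqrt(pi_f(1-pi_f)pi_m(1-pi_m)).  Construction
    fails when the implied table leaves [max(0, pi_f+pi_m-1), min(pi_f, pi_m)]
    (the Frechet bounds) or any cell goes negative.
    """

    pi_f: float
    pi_m: float
    rho: float

    def __post_init__(self):
        self.pi_f = float(self.pi_f)
        self.pi_m = float(self.pi_m)
        self.rho = float(self.rho)
        for name, p in (("pi_f", self.pi_f), ("pi_m", self.pi_m)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho={self.rho} outside [-1, 1]")
        p11 = self.pi_f * self.pi_m + self.rho * math.sqrt(
            self.pi_f * (1 - self.pi_f) * self.pi_m * (1 - self.pi_m)
        )
        lo = max(0.0, self.pi_f + self.pi_m - 1.0)
        hi = min(self.pi_f, self.pi_m)
        if p11 < lo - _MASS_TOL or p11 > hi + _MASS_TOL:
            raise ValueError(
                f"(pi_f={self.pi_f}, pi_m={self.pi_m}, rho={self.rho}) implies "
                f"P(1,1)={p11:.6g} outside the Frechet bounds [{lo:.6g}, {hi:.6g}]"
            )
        p11 = min(max(p11, lo), hi)
        self._tab = {
            (1, 1): p11,
            (1, 0): self.pi_f - p11,
            (0, 1): self.pi_m - p11,
            (0, 0): 1.0 - self.pi_f - self.pi_m + p11,
        }

    @property
    def K(self) -> int:
        return 2

    def mass(self, config: Sequence[int]) -> float:
        bits = self._check_dim(config)
        return self._tab[bits]


@dataclass
class ExplicitTablePrior(JointPrior):
    """A fully enumerated probability table over {0,1}^K."""

    mass_table: Dict[Tuple[int, ...], float] = field(default_factory=dict)

    def __init__(self, mass_table: Dict[Sequence[int], float]):
        if not mass_table:
            raise ValueError("empty prior table")
        tab = {_as_config(k): float(v) for k, v in mass_table.items()}
        Ks = {len(k) for k in tab}
        if len(Ks) != 1:
            raise ValueError(f"configurations of mixed lengths: {sorted(Ks)}")
        K = Ks.pop()
        if K > ENUMERATION_LIMIT:
            raise ValueError(
                f"K={K} exceeds the enumeration limit of {ENUMERATION_LIMIT} tests"
            )
        for cfg, v in tab.items():
            if v < 0:
                raise ValueError(f"negative mass {v} at configuration {cfg}")
        total = math.fsum(tab.values())
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"prior table sums to {total!r}, not 1 (tol 1e-12)")
        self.mass_table = tab
        self._K = K

    @property
    def K(self) -> int:
        return self._K

    def mass(self, config: Sequence[int]) -> float:
        bits = self._check_dim(config)
        return self.mass_table.get(bits, 0.0)


def prior_mass(prior: JointPrior, config: Sequence[int]) -> float:
    """p(theta = config) under the joint prior."""
    return prior.mass(config)


def prior_table(prior: JointPrior) -> Dict[Tuple[int, ...], float]:
    """The full table {config: probability} over all 2^K configurations."""
    return prior.table()


def pairwise_correlation(prior: JointPrior, i: int, j: int) -> float:
    """Pearson correlation of (theta_i, theta_j) computed from the joint table.

    Undefined (raises) when either margin is degenerate (P(theta=1) in {0,1}).
    """
    K = prior.K
    if not (0 <= i < K and 0 <= j < K):
        raise IndexError(f"test indices ({i}, {j}) out of range for K={K}")
    if i == j:
        return 1.0
    tab = prior.table()
    pi_i = sum(v for cfg, v in tab.items() if cfg[i] == 1)
    pi_j = sum(v for cfg, v in tab.items() if cfg[j] == 1)
    e_ij = sum(v for cfg, v in tab.items() if cfg[i] == 1 and cfg[j] == 1)
    var_i = pi_i * (1.0 - pi_i)
    var_j = pi_j * (1.0 - pi_j)
    if var_i <= 0.0 or var_j <= 0.0:
        raise ValueError(
            f"degenerate margin (P={pi_i:.3g}, P={pi_j:.3g}); correlation undefined"
        )
    return (e_ij - pi_i * pi_j) / math.sqrt(var_i * var_j)
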