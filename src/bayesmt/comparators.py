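"""Frequentist multiplicity adjustments: Bonferroni, Holm, Benjamini-Hochberg.

These are the contrast class for the posterior-threshold rule: they operate
on p-values alone and penalize each test by the size of a test family the
analyst must choose, whereas the Bayesian machinery adjusts only through
whatever dependence the prior and the evidence model actually encode.

Bonferroni supports an ``m`` override larger than the number of supplied
p-values, for the common post-hoc situation where a critic counts unreported
tests into the family (e.g. adjusting 8 reported tests for a family of
8 + 16 = 24).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["AdjustmentResult", "bonferroni", "holm", "benjamini_hochberg"]


@dataclass
class AdjustmentResult:
    """Adjusted p-values (capped at 1) and rejection flags at the given level."""

    adjusted: np.ndarray
    reject: np.ndarray
    method: str
    alpha: float
    m: int


def _check_p(p_values: Sequence[float]) -> np.ndarray:
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05, m: Optional[int] = None
) -> AdjustmentResult:
    """Bonferroni: adjusted_j = min(1, m * p_j); reject iff adjusted <= alpha."""
    p = _check_p(p_values)
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError(
            f"family size m={m_eff} smaller than the {p.size} supplied p-values"
        )
    adjusted = np.minimum(1.0, m_eff * p)
    return AdjustmentResult(
        adjusted=adjusted,
        reject=adjusted <= alpha,
        method="bonferroni",
        alpha=alpha,
        m=m_eff,
    )


def holm(p_values: Sequence[float], alpha: float = 0.05) -> AdjustmentResult:
    """Holm step-down; uniformly at least as powerful as Bonferroni."""
    p = _check_p(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj_sorted = np.minimum(1.0, adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustmentResult(
        adjusted=adjusted, reject=adjusted <= alpha, method="holm", alpha=alpha, m=m
    )


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> AdjustmentResult:
    """Benjamini-Hochberg step-up with monotone adjusted p-values (FDR at q)."""
    p = _check_p(p_values)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(1.0, adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustmentResult(
        adjusted=adjusted, reject=adjusted <= q, method="bh", alpha=q, m=m
    )
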