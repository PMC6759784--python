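"""Seeded Monte-Carlo experiments for the multiple-testing machinery.

Three experiments probe the qualitative behavior of posteriors under
dependence and selection, and one reports operating characteristics against
the frequentist comparators:

``run_collider_sim``
    How is theta_f associated with the *other* test's statistic X_m once we
    condition on its own statistic X_f?  Two paths contribute: prior
    association routes through theta_m (same sign as the association), while
    residual correlation of the statistics routes through the conditioned-on
    collider X_f and reverses sign — with both effect and residual
    association positive, conditioning on a stratum of X_f makes theta_f and
    X_m *negatively* associated.
``run_selection_sim``
    A "data fishing" selection rule S reports whichever of two tests has the
    larger marginal posterior.  Because S is a deterministic function of the
    data, theta is conditionally independent of S given the data: the
    posterior needs no selection adjustment and stays calibrated.  The
    frequentist picture differs: among replicates where a truly null test is
    the one selected, its p-value is no longer uniform.
``run_operating_characteristics``
    FWER / power / FDR of the posterior-threshold rule versus unadjusted,
    Bonferroni, Holm and Benjamini-Hochberg testing, over a simulated truth.

``generate_dataset`` writes a single simulated evidence table plus a truth
sidecar; it is the fixture generator used throughout the test suite.

All experiments draw every random number from one master seed via
``numpy.random.SeedSequence`` spawning, and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import benjamini_hochberg, bonferroni, holm
from .evidence import EvidenceModel, simulate_evidence_matrix
from .posterior import marginal_posterior_batch
from .priors import CommonCauseExchangeablePrior, JointPrior, all_configs

__all__ = [
    "ScenarioSpec",
    "ColliderResult",
    "SelectionResult",
    "run_collider_sim",
    "run_selection_sim",
    "run_operating_characteristics",
    "generate_dataset",
    "draw_truths",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative scenario: prior (pi, rho), evidence (mu, residual r), size.

    ``residual_corr`` is the common off-diagonal correlation r of the
    statistics given theta (0 means conditionally independent tests);
    ``window`` is the half-width of the X_f conditioning strata on the z
    scale used by the collider experiment.
    """

    K: int = 2
    pi: float = 0.5
    rho: float = 0.0
    mu: float = 2.0
    residual_corr: float = 0.0
    N: int = 100_000
    seed: int = 0
    window: float = 0.25

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("replicate count N must be >= 1")
        if not self.window > 0:
            raise ValueError("conditioning window width must be positive")

    def prior(self) -> CommonCauseExchangeablePrior:
        return CommonCauseExchangeablePrior(pi=self.pi, rho=self.rho, K=self.K)

    def model(self) -> EvidenceModel:
        R = None
        if self.residual_corr != 0.0:
            R = np.full((self.K, self.K), self.residual_corr)
            np.fill_diagonal(R, 1.0)
        return EvidenceModel(K=self.K, scale="z", mu=self.mu, residual_correlation=R)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def draw_truths(prior: JointPrior, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n indicator vectors theta from the joint prior, shape (n, K)."""
    if isinstance(prior, CommonCauseExchangeablePrior):
        shared_flag = rng.uniform(size=n) < prior.rho
        shared_val = (rng.uniform(size=n) < prior.pi).astype(np.int8)
        iid = (rng.uniform(size=(n, prior.K)) < prior.pi).astype(np.int8)
        out = np.where(shared_flag[:, None], shared_val[:, None], iid)
        return out.astype(np.int8)
    configs = np.array(list(all_configs(prior.K)), dtype=np.int8)
    probs = np.array([prior.mass(tuple(c)) for c in configs], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(configs), size=n, p=probs)
    return configs[idx]


# ---------------------------------------------------------------------------
# collider experiment


@dataclass
class ColliderResult:
    """Partial association of theta_f with X_m given X_f, two ways."""

    stratified_diff: float  # inverse-variance pooled E[X_m|theta_f=1] - E[X_m|theta_f=0]
    stratified_se: float
    partial_corr: float  # linear partial correlation of theta_f and X_m given X_f
    partial_corr_se: float
    n_strata_used: int
    n_replicates: int
    spec: ScenarioSpec

    @property
    def z_stratified(self) -> float:
        return self.stratified_diff / self.stratified_se


def run_collider_sim(spec: ScenarioSpec) -> ColliderResult:
    """Estimate the conditional association of theta_f with X_m given X_f.

    Draws (theta, X) ``spec.N`` times, stratifies on X_f in windows of
    half-width ``spec.window``, and within each stratum contrasts the mean of
    X_m between theta_f = 1 and theta_f = 0 replicates; strata are pooled by
    inverse variance.  A linear partial-correlation summary (theta_f and X_m
    each residualized on X_f) is reported alongside as a robustness check.
    """
    if spec.K != 2:
        raise ValueError("the collider experiment is defined for K=2")
    rng_theta, rng_x = _spawn(spec.seed, 2)
    thetas = draw_truths(spec.prior(), spec.N, rng_theta)
    X = simulate_evidence_matrix(spec.model(), thetas, rng_x)
    xf, xm = X[:, 0], X[:, 1]
    tf = thetas[:, 0].astype(bool)

    width = 2.0 * spec.window
    edges = np.arange(np.floor(xf.min()), np.ceil(xf.max()) + width, width)
    which = np.digitize(xf, edges)
    diffs, variances = [], []
    for b in np.unique(which):
        sel = which == b
        n1 = int(np.sum(tf & sel))
        n0 = int(np.sum(~tf & sel))
        if n1 < 5 or n0 < 5:
            continue
        m1, m0 = xm[tf & sel], xm[~tf & sel]
        diffs.append(m1.mean() - m0.mean())
        variances.append(m1.var(ddof=1) / n1 + m0.var(ddof=1) / n0)
    if not diffs:
        raise ValueError(
            "no X_f stratum contained both theta_f=1 and theta_f=0 replicates; "
            "widen the window or increase N"
        )
    w = 1.0 / np.asarray(variances)
    pooled = float(np.sum(w * np.asarray(diffs)) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))

    # linear partial correlation as the robustness line
    def _resid(y, x):
        slope = np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1)
        return y - slope * (x - x.mean()) - y.mean()

    if tf.all() or (~tf).all():
        pc, pc_se = float("nan"), float("nan")
    else:
        rt = _resid(tf.astype(float), xf)
        rm = _resid(xm, xf)
        pc = float(np.corrcoef(rt, rm)[0, 1])
        pc_se = 1.0 / np.sqrt(spec.N - 3)
    return ColliderResult(
        stratified_diff=pooled,
        stratified_se=pooled_se,
        partial_corr=pc,
        partial_corr_se=pc_se,
        n_strata_used=len(diffs),
        n_replicates=spec.N,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# selection ("data fishing") experiment


@dataclass
class SelectionResult:
    """Posterior calibration under selection + selected-null p-value report."""

    calibration: pd.DataFrame  # bin, n, mean_posterior, freq_alt, binom_se
    ks_statistic: float
    ks_pvalue: float
    ks_critical_001: float
    n_selected_null: int
    n_replicates: int
    spec: ScenarioSpec


def run_selection_sim(spec: ScenarioSpec, n_bins: int = 10) -> SelectionResult:
    """Simulate the report-the-larger-posterior selection rule S (K=2).

    (a) Calibration: among replicates, take the *selected* test's marginal
    posterior q and its true indicator; per posterior bin, the empirical
    alternative frequency should match the mean posterior — selection by S
    requires no correction because S is a function of the data.
    (b) Among replicates where test f is truly null *and* selected, the
    two-sided p-value of X_f is compared to Uniform(0,1) by a KS test.
    """
    if spec.K != 2:
        raise ValueError("the selection experiment is defined for K=2")
    if spec.N == 1:
        warnings.warn("N=1 gives a degenerate selection report", stacklevel=2)
    rng_theta, rng_x = _spawn(spec.seed, 2)
    prior, model = spec.prior(), spec.model()
    thetas = draw_truths(prior, spec.N, rng_theta)
    X = simulate_evidence_matrix(model, thetas, rng_x)
    marg = marginal_posterior_batch(prior, model, X)
    # ties broken toward test f (index 0)
    S = (marg[:, 1] > marg[:, 0]).astype(int)
    rows = np.arange(spec.N)
    q_sel = marg[rows, S]
    theta_sel = thetas[rows, S].astype(bool)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(q_sel, edges) - 1, 0, n_bins - 1)
    recs = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        freq = float(theta_sel[sel].mean())
        qbar = float(q_sel[sel].mean())
        recs.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": n,
                "mean_posterior": qbar,
                "freq_alt": freq,
                "binom_se": float(np.sqrt(max(qbar * (1 - qbar), 1e-12) / n)),
            }
        )
    calibration = pd.DataFrame.from_records(recs)

    null_f_selected = (~thetas[:, 0].astype(bool)) & (S == 0)
    n_sel = int(null_f_selected.sum())
    if n_sel == 0:
        raise ValueError("no replicates with test f null and selected; increase N")
    p_sel = 2.0 * stats.norm.sf(np.abs(X[null_f_selected, 0]))
    ks = stats.kstest(p_sel, "uniform")
    # asymptotic KS critical value at level alpha: sqrt(-ln(alpha/2)/2)/sqrt(n)
    crit = float(np.sqrt(-0.5 * np.log(0.005)) / np.sqrt(n_sel))
    return SelectionResult(
        calibration=calibration,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        ks_critical_001=crit,
        n_selected_null=n_sel,
        n_replicates=spec.N,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# operating characteristics


def run_operating_characteristics(
    spec: ScenarioSpec,
    tau: float = 0.5,
    alpha: float = 0.05,
    truth_all_null: bool = False,
) -> pd.DataFrame:
    """FWER, mean power and FDR for the posterior rule vs p-value procedures.

    The truth is drawn from the scenario prior — or from the all-null
    configuration when ``truth_all_null`` is set, in which case the analyst's
    posterior still uses the stated prior (the classic "all nulls true"
    stress case).  One row per procedure, with Monte-Carlo standard errors.
    """
    rng_theta, rng_x = _spawn(spec.seed, 2)
    prior, model = spec.prior(), spec.model()
    if truth_all_null:
        thetas = np.zeros((spec.N, spec.K), dtype=np.int8)
    else:
        thetas = draw_truths(prior, spec.N, rng_theta)
    X = simulate_evidence_matrix(model, thetas, rng_x)
    marg = marginal_posterior_batch(prior, model, X)
    pvals = 2.0 * stats.norm.sf(np.abs(X))

    alt = thetas.astype(bool)
    null = ~alt
    decisions = {
        "posterior_tau": marg > tau,
        "unadjusted": pvals <= alpha,
        "bonferroni": np.vstack(
            [bonferroni(row, alpha=alpha).reject for row in pvals]
        ),
        "holm": np.vstack([holm(row, alpha=alpha).reject for row in pvals]),
        "bh": np.vstack([benjamini_hochberg(row, q=alpha).reject for row in pvals]),
    }
    recs = []
    n = spec.N
    for method, rej in decisions.items():
        false_any = np.any(rej & null, axis=1)
        fwer = float(false_any.mean())
        n_alt = alt.sum()
        power = float((rej & alt).sum() / n_alt) if n_alt else float("nan")
        n_rej = rej.sum(axis=1)
        fdr_terms = np.where(n_rej > 0, (rej & null).sum(axis=1) / np.maximum(n_rej, 1), 0.0)
        recs.append(
            {
                "method": method,
                "fwer": fwer,
                "fwer_se": float(np.sqrt(fwer * (1 - fwer) / n)),
                "power": power,
                "fdr": float(fdr_terms.mean()),
                "fdr_se": float(fdr_terms.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(
    spec: ScenarioSpec,
    rng_seed: int,
    evidence_path,
    truth_path,
) -> Tuple[Path, Path]:
    """Write one simulated evidence table and its truth sidecar to disk.

    The evidence file has columns ``test_id,z``; the truth file
    ``test_id,theta``.  Repeated calls with the same spec and seed produce
    byte-identical files.
    """
    rng_theta, rng_x = _spawn(rng_seed, 2)
    theta = draw_truths(spec.prior(), 1, rng_theta)[0]
    x = simulate_evidence_matrix(spec.model(), theta[None, :], rng_x)[0]
    evidence_path, truth_path = Path(evidence_path), Path(truth_path)
    with open(evidence_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("test_id,z\n")
        for j, v in enumerate(x):
            fh.write(f"t{j + 1},{v:.17g}\n")
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("test_id,theta\n")
        for j, b in enumerate(theta):
            fh.write(f"t{j + 1},{int(b)}\n")
    return evidence_path, truth_path
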