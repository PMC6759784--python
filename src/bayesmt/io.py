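"""Delimited-file readers/writers and config parsing.

File conventions: comma-separated UTF-8 with a mandatory header row and "."
decimal.  Evidence tables carry a ``test_id`` column plus exactly one of the
accepted statistic schemas: ``z``, ``p``, or ``estimate,ci_lower,ci_upper``
(ratio scale with a two-sided CI, converted to Wald z).

Configs are YAML key-value documents with up to three blocks — ``prior``,
``evidence``, ``scenario`` — validated in one pass; all violations are
reported together rather than stopping at the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .evidence import EvidenceModel, EvidenceVector
from .posthoc import RatioEstimate, se_from_ci
from .priors import (
    CommonCauseExchangeablePrior,
    ExplicitTablePrior,
    IndependentPrior,
    JointPrior,
    PairwisePrior,
)
from .simulators import ScenarioSpec

__all__ = ["read_evidence", "write_results", "load_config", "ConfigError", "LoadedConfig"]

_SCHEMAS = {
    "z": ("z",),
    "p": ("p",),
    "ratio": ("estimate", "ci_lower", "ci_upper"),
}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


def read_evidence(path, level: float = 0.95) -> Tuple[EvidenceVector, pd.DataFrame]:
    """Read an evidence table; returns the vector plus per-row metadata.

    Ratio-scale rows are converted to Wald z via the log-CI standard error.
    Values round-trip at full double precision.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"test_id": str})
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = set(df.columns)
    if "test_id" not in cols:
        raise ValueError(f"{path}: missing required column 'test_id'")
    stat_cols = cols - {"test_id"}
    matches = [name for name, req in _SCHEMAS.items() if stat_cols == set(req)]
    if not matches:
        raise ValueError(
            f"{path}: columns {sorted(stat_cols)} match no accepted schema "
            f"(one of {[list(v) for v in _SCHEMAS.values()]}); mixed or unknown "
            "columns are rejected"
        )
    schema = matches[0]
    for col in _SCHEMAS[schema]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if df[col].isna().any() or len(bad):
            row = int((list(bad) or df.index[df[col].isna()])[0])
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"row {row + 2} (1-based, counting the header)"
            )
        df[col] = numeric

    if schema == "z":
        vec = EvidenceVector(df["z"].to_numpy(), scale="z")
    elif schema == "p":
        vec = EvidenceVector(df["p"].to_numpy(), scale="p")
    else:
        log_est, ses = [], []
        for i, row in df.iterrows():
            r = RatioEstimate(
                estimate=row["estimate"],
                ci_lower=row["ci_lower"],
                ci_upper=row["ci_upper"],
                level=level,
                label=row["test_id"],
            )
            log_est.append(math.log(r.estimate))
            ses.append(se_from_ci(r))
        vec = EvidenceVector(log_est, scale="log_ratio_with_se", se=ses).to_z()
    return vec, df


def write_results(path, table: pd.DataFrame, header_lines: Optional[List[str]] = None):
    """Write a results table as CSV, with optional '#'-prefixed header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)
    return path


@dataclass
class LoadedConfig:
    """Validated objects built from a YAML config document."""

    prior: Optional[JointPrior] = None
    evidence_model: Optional[EvidenceModel] = None
    scenario: Optional[ScenarioSpec] = None
    raw: Dict[str, Any] = None


def _build_prior(block: Dict[str, Any], errors: List[str]) -> Optional[JointPrior]:
    kind = block.get("kind")
    try:
        if kind == "independent":
            return IndependentPrior(pi=block["pi"])
        if kind == "common_cause":
            return CommonCauseExchangeablePrior(
                pi=block["pi"], rho=block.get("rho", 0.0), K=block.get("K", 2)
            )
        if kind == "pairwise":
            return PairwisePrior(
                pi_f=block["pi_f"], pi_m=block["pi_m"], rho=block.get("rho", 0.0)
            )
        if kind == "explicit":
            raw = block["table"]
            if isinstance(raw, str):
                raw = dict(
                    line.split(",") for line in raw.strip().splitlines() if line.strip()
                )
            tab = {tuple(int(c) for c in str(k).strip()): float(v) for k, v in raw.items()}
            total = math.fsum(tab.values())
            if abs(total - 1.0) > 1e-12:
                errors.append(f"prior: explicit table sums to {total!r}, not 1")
                return None
            return ExplicitTablePrior(tab)
        errors.append(
            f"prior: unknown kind {kind!r} (expected independent, common_cause, "
            "explicit or pairwise)"
        )
    except KeyError as exc:
        errors.append(f"prior: missing required key {exc}")
    except (ValueError, TypeError) as exc:
        errors.append(f"prior: {exc}")
    return None


def _build_evidence(
    block: Dict[str, Any], K: Optional[int], errors: List[str]
) -> Optional[EvidenceModel]:
    try:
        K_eff = int(block.get("K", K if K is not None else 2))
        R = None
        r = block.get("residual_corr")
        if r is not None:
            r = np.asarray(r, dtype=float)
            if r.ndim == 0:
                R = np.full((K_eff, K_eff), float(r))
                np.fill_diagonal(R, 1.0)
            else:
                R = r
        return EvidenceModel(
            K=K_eff,
            scale=block.get("scale", "z"),
            mu=block.get("mu"),
            a=block.get("a"),
            residual_correlation=R,
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"evidence: {exc}")
    return None


def _build_scenario(block: Dict[str, Any], errors: List[str]) -> Optional[ScenarioSpec]:
    try:
        allowed = {"K", "pi", "rho", "mu", "residual_corr", "N", "seed", "window"}
        unknown = set(block) - allowed
        if unknown:
            errors.append(f"scenario: unknown keys {sorted(unknown)}")
            return None
        return ScenarioSpec(**{k: block[k] for k in block})
    except (ValueError, TypeError) as exc:
        errors.append(f"scenario: {exc}")
    return None


def load_config(path) -> LoadedConfig:
    """Parse and validate a YAML config; all errors are raised together."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    errors: List[str] = []
    out = LoadedConfig(raw=doc)
    if "prior" in doc:
        out.prior = _build_prior(doc["prior"] or {}, errors)
    if "evidence" in doc:
        K = out.prior.K if out.prior is not None else None
        out.evidence_model = _build_evidence(doc["evidence"] or {}, K, errors)
    if "scenario" in doc:
        out.scenario = _build_scenario(doc["scenario"] or {}, errors)
    if (
        out.prior is not None
        and out.evidence_model is not None
        and out.prior.K != out.evidence_model.K
    ):
        errors.append(
            f"prior K={out.prior.K} and evidence K={out.evidence_model.K} disagree"
        )
    if errors:
        raise ConfigError(errors)
    return out
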