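"""Fixed-effect and DerSimonian-Laird random-effects pooling of log odds ratios.

Implements inverse-variance pooling, Cochran's Q / I^2 / tau^2 heterogeneity
statistics, a configurable fixed-vs-random model-selection policy, the
sensitivity suite (leave-one-out, drop-first-published, drop-HWE-violating),
cumulative meta-analysis in publication order, subgroup pooling, and a simple
weighted meta-regression.

The fixed-effect estimator is inverse-variance on the log-OR scale; a
Mantel-Haenszel pooled OR over raw 2x2 tables is available as an alternative.
The between-study variance tau^2 is the DerSimonian-Laird moment estimator
throughout (no Knapp-Hartung adjustment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .study_effects import (
    EffectEstimate,
    Z_95,
    allele_table_from_genotypes,
    effect_from_record,
    hwe_test,
)

__all__ = [
    "MetaResult",
    "HetStats",
    "ModelPolicy",
    "SensitivityReport",
    "pool_fixed",
    "pool_random_dl",
    "heterogeneity",
    "select_model",
    "pool",
    "mantel_haenszel_or",
    "evidence_amount",
    "sensitivity_suite",
    "cumulative_by_year",
    "subgroup",
    "meta_regression",
    "forest_table",
]


class HetStats(NamedTuple):
    """Cochran's Q with its p-value, I^2 (percent) and DL tau^2."""

    q_stat: float
    q_p: float
    i_squared_pct: float
    tau2: float


@dataclass(frozen=True)
class MetaResult:
    """A pooled association estimate with heterogeneity diagnostics."""

    k: int
    pooled_log_or: float
    pooled_se: float
    or_pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    q_stat: float
    q_p: float
    i_squared_pct: float
    tau2: float
    model: str  # "fixed" | "random"
    evidence_amount: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class ModelPolicy:
    """Rule deciding between fixed and random effects from heterogeneity.

    Default: random effects when I^2 exceeds 50% or the Q-test p-value falls
    below 0.10, fixed effects otherwise.
    """

    i2_threshold: float = 50.0
    qp_threshold: float = 0.10

    def choose(self, het: HetStats) -> str:
        if het.i_squared_pct > self.i2_threshold or het.q_p < self.qp_threshold:
            return "random"
        return "fixed"


@dataclass(frozen=True)
class SensitivityReport:
    """Stability of a pooled association under the standard exclusions."""

    loo_or_range: tuple[float, float]
    drop_first_or: Optional[float]
    drop_hwe_or: Optional[float]
    stable: bool
    skipped: bool = False
    reason: str = ""


def _thetas_and_ses(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValueError("no effect estimates to pool")
    theta = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be finite and positive")
    return theta, se


def _assemble(
    theta_hat: float,
    se_hat: float,
    k: int,
    het: HetStats,
    model: str,
    evidence: int,
) -> MetaResult:
    z = theta_hat / se_hat
    p = 2 * stats.norm.sf(abs(z))
    return MetaResult(
        k=k,
        pooled_log_or=theta_hat,
        pooled_se=se_hat,
        or_pooled=math.exp(theta_hat),
        ci_low=math.exp(theta_hat - Z_95 * se_hat),
        ci_high=math.exp(theta_hat + Z_95 * se_hat),
        p_value=max(p, np.finfo(float).tiny),
        q_stat=het.q_stat,
        q_p=het.q_p,
        i_squared_pct=het.i_squared_pct,
        tau2=het.tau2,
        model=model,
        evidence_amount=evidence,
    )


def heterogeneity(effects: Sequence[EffectEstimate]) -> HetStats:
    """Cochran's Q, its chi-square p (k-1 df), I^2 and the DL tau^2.

    Q is computed with fixed-effect inverse-variance weights;
    I^2 = max(0, (Q - (k-1))/Q) * 100;
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))).
    """
    theta, se = _thetas_and_ses(effects)
    k = len(theta)
    if k < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    w = 1.0 / se**2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    q_p = float(stats.chi2.sf(q, df=k - 1))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return HetStats(q_stat=q, q_p=q_p, i_squared_pct=i2, tau2=tau2)


def _degenerate_het() -> HetStats:
    # single-study pools: Q undefined, reported as zero with p = 1
    return HetStats(q_stat=0.0, q_p=1.0, i_squared_pct=0.0, tau2=0.0)


def pool_fixed(effects: Sequence[EffectEstimate], evidence: int = 0) -> MetaResult:
    """Inverse-variance fixed-effect pooled log OR with 95% normal CI."""
    theta, se = _thetas_and_ses(effects)
    k = len(theta)
    w = 1.0 / se**2
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se_hat = float(1.0 / math.sqrt(np.sum(w)))
    het = heterogeneity(effects) if k >= 2 else _degenerate_het()
    return _assemble(theta_hat, se_hat, k, het, "fixed", evidence)


def pool_random_dl(effects: Sequence[EffectEstimate], evidence: int = 0) -> MetaResult:
    """DerSimonian-Laird random-effects pooled log OR.

    Weights 1/(se_i^2 + tau^2) with the moment estimator of tau^2; collapses
    to the fixed-effect answer when tau^2 = 0.
    """
    theta, se = _thetas_and_ses(effects)
    k = len(theta)
    if k < 2:
        raise ValueError("random-effects pooling requires at least 2 studies")
    het = heterogeneity(effects)
    w = 1.0 / (se**2 + het.tau2)
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se_hat = float(1.0 / math.sqrt(np.sum(w)))
    return _assemble(theta_hat, se_hat, k, het, "random", evidence)


def select_model(het: HetStats, policy: ModelPolicy = ModelPolicy()) -> str:
    """Apply the configured fixed-vs-random policy to heterogeneity statistics."""
    return policy.choose(het)


def pool(
    effects: Sequence[EffectEstimate],
    policy: ModelPolicy = ModelPolicy(),
    evidence: int = 0,
) -> MetaResult:
    """Pool under the model the policy selects (fixed for single studies)."""
    if len(effects) < 2:
        return pool_fixed(effects, evidence)
    het = heterogeneity(effects)
    if select_model(het, policy) == "random":
        return pool_random_dl(effects, evidence)
    return pool_fixed(effects, evidence)


def mantel_haenszel_or(tables: Sequence[tuple[float, float, float, float]]) -> float:
    """Mantel-Haenszel pooled odds ratio over raw 2x2 tables (a, b, c, d)."""
    num = den = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        if n == 0:
            raise ValueError("empty 2x2 table")
        num += a * d / n
        den += b * c / n
    if den == 0:
        raise ValueError("Mantel-Haenszel denominator is zero")
    return num / den


def evidence_amount(records: Iterable, mode: str = "alleles") -> int:
    """Amount of evidence behind an association.

    ``alleles`` (default): total count of test (minor) alleles among cases and
    controls, summed over studies with genotype counts; ``genotypes``: total
    count of genotyped individuals instead.  Studies contributing only a
    reported OR carry no countable alleles and contribute zero.
    """
    total = 0
    for r in records:
        if not getattr(r, "has_counts", False):
            continue
        if mode == "alleles":
            a, _, c, _ = allele_table_from_genotypes(r.case_counts, r.control_counts)
            total += a + c
        elif mode == "genotypes":
            total += sum(r.case_counts) + sum(r.control_counts)
        else:
            raise ValueError(f"unknown evidence mode {mode!r}")
    return int(total)


def _publication_order(records) -> list:
    return sorted(records, key=lambda r: (r.year, r.author, r.study_id))


def sensitivity_suite(
    records: Sequence,
    policy: ModelPolicy = ModelPolicy(),
    hwe_threshold: float = 0.05,
    prefer: str = "counts",
) -> SensitivityReport:
    """Leave-one-out, drop-first-published and drop-HWE-violating re-pooling.

    ``stable`` is true iff every re-pooled variant keeps the direction of the
    full-analysis estimate and, whenever the full CI excludes 1, so does the
    variant's CI.  The first published study is the minimum of
    (year, author, study_id).  HWE violation means control-arm chi-square
    p below ``hwe_threshold``; records without counts cannot violate it.
    """
    records = list(records)
    if len(records) < 2:
        return SensitivityReport(
            loo_or_range=(math.nan, math.nan), drop_first_or=None, drop_hwe_or=None,
            stable=True, skipped=True, reason="fewer than 2 studies",
        )
    effects = {r.study_id: effect_from_record(r, prefer=prefer) for r in records}
    full = pool(list(effects.values()), policy)
    full_sig = full.ci_low > 1 or full.ci_high < 1
    direction = 1.0 if full.pooled_log_or >= 0 else -1.0

    variants: list[MetaResult] = []
    loo_ors: list[float] = []
    for r in records:
        rest = [effects[x.study_id] for x in records if x.study_id != r.study_id]
        m = pool(rest, policy)
        variants.append(m)
        loo_ors.append(m.or_pooled)

    first = _publication_order(records)[0]
    rest = [effects[x.study_id] for x in records if x.study_id != first.study_id]
    drop_first = pool(rest, policy) if rest else None
    if drop_first is not None:
        variants.append(drop_first)

    def violates(r) -> bool:
        if not r.has_counts:
            return False
        p = r.hwe_p if r.hwe_p is not None else hwe_test(r.control_counts)
        return p < hwe_threshold

    keep = [effects[r.study_id] for r in records if not violates(r)]
    drop_hwe = pool(keep, policy) if keep else None
    if drop_hwe is not None:
        variants.append(drop_hwe)

    stable = all(
        (m.pooled_log_or * direction >= 0 or abs(m.pooled_log_or) < 1e-12)
        and (not full_sig or m.ci_low > 1 or m.ci_high < 1)
        for m in variants
    )
    return SensitivityReport(
        loo_or_range=(min(loo_ors), max(loo_ors)),
        drop_first_or=None if drop_first is None else drop_first.or_pooled,
        drop_hwe_or=None if drop_hwe is None else drop_hwe.or_pooled,
        stable=stable,
    )


def cumulative_by_year(
    records: Sequence,
    policy: ModelPolicy = ModelPolicy(),
    prefer: str = "counts",
) -> list[MetaResult]:
    """Cumulative meta-analysis: element j pools the first j studies in
    (year, author, study_id) order, showing how evidence accrues."""
    ordered = _publication_order(records)
    out: list[MetaResult] = []
    for j in range(1, len(ordered) + 1):
        prefix = ordered[:j]
        effects = [effect_from_record(r, prefer=prefer) for r in prefix]
        out.append(pool(effects, policy, evidence=evidence_amount(prefix)))
    return out


def subgroup(
    records: Sequence,
    key: str,
    policy: ModelPolicy = ModelPolicy(),
    prefer: str = "counts",
) -> dict[str, MetaResult]:
    """Independent pooled result per stratum of ``key`` (ethnicity or design)."""
    if key not in {"ethnicity", "design"}:
        raise ValueError("subgroup key must be 'ethnicity' or 'design'")
    strata: dict[str, list] = {}
    for r in records:
        strata.setdefault(getattr(r, key), []).append(r)
    out: dict[str, MetaResult] = {}
    for label, group in sorted(strata.items()):
        effects = [effect_from_record(r, prefer=prefer) for r in group]
        out[label] = pool(effects, policy, evidence=evidence_amount(group))
    return out


def meta_regression(
    effects: Sequence[EffectEstimate],
    covariate: Sequence[float],
) -> tuple[float, float, float]:
    """Weighted linear regression of study log ORs on one covariate.

    Weights are 1/(se_i^2 + tau^2) with tau^2 from the intercept-only DL
    model; the slope's standard error comes from the weighted normal
    equations with the scale fixed at 1, and its p-value from the normal
    distribution.

    Returns ``(slope, slope_se, p_value)``.
    """
    theta, se = _thetas_and_ses(effects)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(theta):
        raise ValueError("covariate length must match the number of studies")
    if len(theta) < 3:
        raise ValueError("meta-regression requires at least 3 studies")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: slope is not identifiable")
    tau2 = heterogeneity(effects).tau2
    w = 1.0 / (se**2 + tau2)
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * theta))
    cov = np.linalg.inv(xtwx)
    slope = float(beta[1])
    slope_se = float(math.sqrt(cov[1, 1]))
    p = float(2 * stats.norm.sf(abs(slope / slope_se)))
    return slope, slope_se, p


def forest_table(records: Sequence, policy: ModelPolicy = ModelPolicy(), prefer: str = "counts"):
    """Per-study rows behind a forest plot: OR, CI and percent weight."""
    import pandas as pd

    effects = [effect_from_record(r, prefer=prefer) for r in records]
    full = pool(effects, policy)
    tau2 = full.tau2 if full.model == "random" else 0.0
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    w_pct = 100.0 * w / w.sum()
    rows = []
    for e, wp in zip(effects, w_pct):
        lo, hi = e.ci()
        rows.append(
            {
                "study_id": e.study_id,
                "year": e.year,
                "or": e.odds_ratio,
                "ci_low": lo,
                "ci_high": hi,
                "weight_pct": wp,
            }
        )
    return pd.DataFrame(rows)
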