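"""Genetic model-free estimation of the mode of inheritance.

Per-genotype odds ratios OR1 (heterozygote vs common homozygote) and OR2
(rare homozygote vs common homozygote) are pooled across studies, and their
ratio on the log scale, lambda = log OR1 / log OR2, indexes the inheritance
model: lambda ~ 0 recessive, ~ 0.5 additive/codominant, ~ 1 dominant.

The two contrasts are pooled independently by DerSimonian-Laird random
effects; the within-study correlation induced by the shared reference
genotype is respected empirically by a nonparametric bootstrap over studies
(resample studies, re-pool both contrasts, recompute lambda), which also
supplies the percentile confidence interval.  This is an approximation to a
bivariate random-effects likelihood, chosen for robustness and testability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .meta_engine import pool_random_dl
from .study_effects import EffectEstimate, genotype_ors

__all__ = [
    "GeneticModelEstimate",
    "pool_genotype_effects",
    "lambda_estimate",
    "classify_model",
    "model_free_analysis",
]

#: |pooled log OR2| below this floor makes lambda numerically meaningless.
DEFAULT_LAMBDA_FLOOR = 0.10
DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class GeneticModelEstimate:
    pooled_log_or1: float
    pooled_log_or2: float
    lambda_: Optional[float]
    lambda_ci: Optional[tuple[float, float]]
    model_class: str
    reason: str = ""


def _pool_pair(
    or1_effects: Sequence[EffectEstimate], or2_effects: Sequence[EffectEstimate]
) -> tuple[float, float]:
    if len(or1_effects) < 2:
        raise ValueError("model-free pooling requires at least 2 studies with counts")
    m1 = pool_random_dl(or1_effects)
    m2 = pool_random_dl(or2_effects)
    return m1.pooled_log_or, m2.pooled_log_or


def pool_genotype_effects(
    records: Sequence, correction: str = "haldane"
) -> tuple[float, float, list[EffectEstimate], list[EffectEstimate]]:
    """Pool OR1 and OR2 across studies with genotype counts.

    Returns the pooled log ORs and the per-study effect lists (for the
    bootstrap).  Studies without genotype counts cannot contribute.
    """
    with_counts = [r for r in records if r.has_counts]
    if len(with_counts) < 2:
        raise ValueError(
            f"model-free analysis needs >= 2 studies with genotype counts, "
            f"found {len(with_counts)}"
        )
    or1_effects: list[EffectEstimate] = []
    or2_effects: list[EffectEstimate] = []
    for r in with_counts:
        e1, e2 = genotype_ors(
            r.case_counts, r.control_counts, correction, study_id=r.study_id, year=r.year
        )
        or1_effects.append(e1)
        or2_effects.append(e2)
    l1, l2 = _pool_pair(or1_effects, or2_effects)
    return l1, l2, or1_effects, or2_effects


def lambda_estimate(
    pooled_log_or1: float,
    pooled_log_or2: float,
    or1_effects: Sequence[EffectEstimate],
    or2_effects: Sequence[EffectEstimate],
    n_boot: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    floor: float = DEFAULT_LAMBDA_FLOOR,
) -> tuple[Optional[float], Optional[tuple[float, float]], str]:
    """lambda = log OR1 / log OR2 with a studywise bootstrap percentile CI.

    Returns ``(lambda, (ci_low, ci_high), reason)``; lambda is None with a
    reason when |pooled log OR2| is below the floor (the ratio would be
    dominated by noise).
    """
    if seed is None:
        raise ValueError("a bootstrap seed is mandatory for reproducibility")
    if abs(pooled_log_or2) <= floor:
        return None, None, f"|log OR2| = {abs(pooled_log_or2):.3f} <= floor {floor}"
    lam = pooled_log_or1 / pooled_log_or2
    k = len(or1_effects)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, k, size=k)
        b1 = [or1_effects[i] for i in idx]
        b2 = [or2_effects[i] for i in idx]
        try:
            l1, l2 = _pool_pair(b1, b2)
        except (ValueError, ZeroDivisionError):
            continue
        if abs(l2) > 1e-12:
            draws.append(l1 / l2)
    if len(draws) < max(50, n_boot // 10):
        return lam, None, "bootstrap produced too few valid resamples"
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return lam, (float(lo), float(hi)), ""


def classify_model(
    lambda_: Optional[float], lambda_ci: Optional[tuple[float, float]]
) -> str:
    """Classify the inheritance model from lambda and its CI.

    recessive when the CI lies within (-0.25, 0.25); additive-codominant
    within (0.25, 0.75); dominant within (0.75, 1.25); beyond-range when the
    CI excludes the whole [0, 1] interval; undetermined otherwise.
    """
    if lambda_ is None or lambda_ci is None:
        return "undetermined"
    lo, hi = lambda_ci
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
        return "undetermined"
    if -0.25 < lo and hi < 0.25:
        return "recessive"
    if 0.25 < lo and hi < 0.75:
        return "additive-codominant"
    if 0.75 < lo and hi < 1.25:
        return "dominant"
    if hi < 0 or lo > 1:
        return "beyond-range"
    return "undetermined"


def model_free_analysis(
    records: Sequence,
    n_boot: int = DEFAULT_N_BOOT,
    seed: Optional[int] = None,
    floor: float = DEFAULT_LAMBDA_FLOOR,
    correction: str = "haldane",
) -> GeneticModelEstimate:
    """End-to-end model-free analysis for one association's study set."""
    l1, l2, e1, e2 = pool_genotype_effects(records, correction)
    lam, ci, reason = lambda_estimate(l1, l2, e1, e2, n_boot=n_boot, seed=seed, floor=floor)
    return GeneticModelEstimate(
        pooled_log_or1=l1,
        pooled_log_or2=l2,
        lambda_=lam,
        lambda_ci=ci,
        model_class=classify_model(lam, ci),
        reason=reason,
    )
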