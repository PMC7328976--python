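"""False positive report probability (FPRP) for genetic association findings.

FPRP is the posterior probability that a nominally significant association is
a false positive, given the observed p-value (used as the significance level
alpha), the statistical power to detect a specified plausible odds ratio at
that level, and a prior probability that the association is real:

    FPRP = alpha (1 - prior) / [alpha (1 - prior) + power * prior]

Power is evaluated on the log-OR scale against a two-sided normal rejection
region.  Categories follow the convention FPRP < 0.05 (strong evidence of a
true association), 0.05 <= FPRP <= 0.20 (moderate), FPRP > 0.20 (weak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .study_effects import log_or_from_ci

__all__ = [
    "FprpResult",
    "DEFAULT_PRIORS",
    "power_at",
    "fprp_value",
    "categorize_fprp",
    "fprp_for_association",
    "fprp_from_summary",
]

#: Prior-probability grid over which FPRP is tabulated.
DEFAULT_PRIORS = (0.25, 0.1, 0.05, 0.01, 0.001)
DEFAULT_HEADLINE_PRIOR = 0.05
DEFAULT_TARGET_OR = 1.5


@dataclass(frozen=True)
class FprpResult:
    observed_p: float
    se_log_or: float
    target_or: float
    power: float
    priors: tuple[float, ...]
    fprp_values: tuple[float, ...]
    headline_prior: float
    headline_fprp: float
    category: str
    degenerate: bool = False


def power_at(alpha: float, se: float, target_log_or: float) -> float:
    """Power of the two-sided level-``alpha`` z-test when the true log OR is
    ``target_log_or`` and the estimator's standard error is ``se``.

    power = 1 - Phi(z* - delta) + Phi(-z* - delta), delta = |target|/se.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if not (se > 0 and math.isfinite(se)):
        raise ValueError("se must be positive and finite")
    z_star = stats.norm.isf(alpha / 2)
    delta = abs(target_log_or) / se
    return float(stats.norm.sf(z_star - delta) + stats.norm.cdf(-z_star - delta))


def fprp_value(alpha: float, power: float, prior: float) -> float:
    """Wacholder's false positive report probability."""
    if not 0 < prior < 1:
        raise ValueError("prior must lie strictly between 0 and 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if not 0 < power <= 1:
        raise ValueError("power must lie in (0, 1]")
    num = alpha * (1 - prior)
    return num / (num + power * prior)


def categorize_fprp(value: float) -> str:
    """Map an FPRP value onto the three-level evidence category."""
    if value < 0.05:
        return "<0.05"
    if value <= 0.20:
        return "0.05–0.20"
    return ">0.20"


def fprp_for_association(
    p_value: float,
    se_log_or: float,
    pooled_or: float = 1.5,
    priors: Sequence[float] = DEFAULT_PRIORS,
    target_or: float = DEFAULT_TARGET_OR,
    headline_prior: float = DEFAULT_HEADLINE_PRIOR,
) -> FprpResult:
    """FPRP over a grid of priors for one pooled association.

    ``alpha`` is the observed two-sided p-value.  The detectable effect is
    ``target_or`` for risk associations and ``1/target_or`` for protective
    ones (``pooled_or`` < 1); on the log scale these are symmetric, so only
    the magnitude matters for power.  A degenerate p-value of 1 maps straight
    to the ">0.20" category.
    """
    if headline_prior not in priors:
        priors = tuple(priors) + (headline_prior,)
    priors = tuple(sorted(set(priors), reverse=True))
    if p_value >= 1.0:
        return FprpResult(
            observed_p=1.0, se_log_or=se_log_or, target_or=target_or, power=1.0,
            priors=priors, fprp_values=tuple(1 - p for p in priors),
            headline_prior=headline_prior, headline_fprp=1 - headline_prior,
            category=">0.20", degenerate=True,
        )
    effective_target = target_or if pooled_or >= 1 else 1.0 / target_or
    pw = power_at(p_value, se_log_or, math.log(effective_target))
    values = tuple(fprp_value(p_value, pw, prior) for prior in priors)
    headline = fprp_value(p_value, pw, headline_prior)
    return FprpResult(
        observed_p=p_value, se_log_or=se_log_or, target_or=effective_target, power=pw,
        priors=priors, fprp_values=values,
        headline_prior=headline_prior, headline_fprp=headline,
        category=categorize_fprp(headline),
    )


def fprp_from_summary(
    or_pooled: float,
    ci_low: float,
    ci_high: float,
    priors: Sequence[float] = DEFAULT_PRIORS,
    target_or: float = DEFAULT_TARGET_OR,
    headline_prior: float = DEFAULT_HEADLINE_PRIOR,
) -> FprpResult:
    """FPRP from a published OR and 95% CI alone.

    The standard error is recovered from the CI width on the log scale and
    alpha is the two-sided p-value recomputed from OR and SE.
    """
    log_or, se = log_or_from_ci(or_pooled, ci_low, ci_high)
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    p = min(max(p, 1e-300), 1.0)
    return fprp_for_association(
        p, se, pooled_or=or_pooled, priors=priors,
        target_or=target_or, headline_prior=headline_prior,
    )
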