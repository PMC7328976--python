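"""Harbord's modified regression test for small-study effects.

For each study's 2x2 table the efficient score of the log odds ratio,
Z = a - (a+b)(a+c)/n, and its variance under the null,
V = (a+b)(c+d)(a+c)(b+d) / (n^2 (n-1)), are computed; the test regresses
Z/sqrt(V) on sqrt(V) by ordinary least squares and examines the intercept.
A non-zero intercept indicates that smaller studies report systematically
different effects (funnel-plot asymmetry), the signature of publication bias
in case-control meta-analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .study_effects import DegenerateTableError

__all__ = ["HarbordResult", "score_and_variance", "harbord_test"]


@dataclass(frozen=True)
class HarbordResult:
    intercept: Optional[float]
    intercept_se: Optional[float]
    t_stat: Optional[float]
    p_value: Optional[float]
    k_used: int
    skipped: bool = False
    reason: str = ""


def score_and_variance(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Efficient score Z and its null variance V for one 2x2 table.

    Z is the observed minus expected count of exposed cases under the
    no-association null; V is the hypergeometric variance of that count.
    """
    n = a + b + c + d
    if n <= 1:
        raise DegenerateTableError("table total must exceed 1")
    margins = (a + b, c + d, a + c, b + d)
    if any(m <= 0 for m in margins):
        raise DegenerateTableError("all four margins must be positive")
    z = a - (a + b) * (a + c) / n
    v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    return float(z), float(v)


def harbord_test(
    tables: Sequence[tuple[float, float, float, float]],
    min_k: int = 3,
    n_excluded: int = 0,
) -> HarbordResult:
    """Harbord small-study-effects test over a set of 2x2 tables.

    Regresses y_i = Z_i/sqrt(V_i) on x_i = sqrt(V_i) by unweighted OLS; the
    intercept estimates the small-study effect and its two-sided p-value uses
    the t distribution with k-2 degrees of freedom.  Skipped (without
    estimates) when fewer than ``min_k`` tables are available;
    ``n_excluded`` records studies that could not contribute (e.g. reported
    OR only, no counts) for the skip/warning report.
    """
    k = len(tables)
    if k < max(min_k, 3):
        reason = f"only {k} studies with counts (min_k={min_k}"
        if n_excluded:
            reason += f", {n_excluded} excluded for missing counts"
        reason += ")"
        return HarbordResult(None, None, None, None, k_used=k, skipped=True, reason=reason)
    zv = [score_and_variance(*t) for t in tables]
    v = np.array([t[1] for t in zv])
    y = np.array([t[0] for t in zv]) / np.sqrt(v)
    x = np.sqrt(v)
    if np.ptp(x) == 0:
        raise ValueError("all studies have identical score variance: regression undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = k - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    intercept = float(beta[0])
    se = float(math.sqrt(cov[0, 0]))
    t_stat = intercept / se
    p = float(2 * stats.t.sf(abs(t_stat), df=df))
    reason = f"{n_excluded} studies excluded for missing counts" if n_excluded else ""
    return HarbordResult(
        intercept=intercept, intercept_se=se, t_stat=t_stat, p_value=p,
        k_used=k, skipped=False, reason=reason,
    )
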