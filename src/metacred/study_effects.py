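"""Per-study effect estimation from genotype tables, and Hardy-Weinberg testing.

All contrasts are expressed as log odds ratios with large-sample standard
errors.  The default contrast is the minor-allele (test-allele) 2x2 table;
per-genotype contrasts against the common-homozygote reference serve the
genetic model-free analysis downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "EffectEstimate",
    "DegenerateTableError",
    "allele_table_from_genotypes",
    "odds_ratio_2x2",
    "genotype_ors",
    "hwe_test",
    "effect_from_record",
    "log_or_from_ci",
]

#: z quantile for a two-sided 95% interval.
Z_95 = stats.norm.ppf(0.975)


class DegenerateTableError(ValueError):
    """A 2x2 (sub)table has no information about the odds ratio."""


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and provenance."""

    log_or: float
    se: float
    contrast: str  # allele | het-vs-common-hom | rare-hom-vs-common-hom | carrier | reported
    study_id: str = ""
    year: int = 0
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be positive and finite, got {self.se}")
        if not math.isfinite(self.log_or):
            raise ValueError("log OR must be finite")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return math.exp(self.log_or - z * self.se), math.exp(self.log_or + z * self.se)


def allele_table_from_genotypes(
    counts_case: Sequence[int], counts_control: Sequence[int]
) -> tuple[int, int, int, int]:
    """Collapse genotype triples into the minor-allele 2x2 table.

    Returns ``(a, b, c, d)`` = (case minor, case major, control minor,
    control major) allele counts; each arm's total equals twice its number of
    genotyped individuals.
    """
    for arm in (counts_case, counts_control):
        if len(arm) != 3 or any(c < 0 for c in arm):
            raise ValueError("genotype counts must be 3 non-negative integers")
    if sum(counts_case) == 0 or sum(counts_control) == 0:
        raise DegenerateTableError("an arm has no genotyped individuals")
    a = 2 * counts_case[2] + counts_case[1]
    b = 2 * counts_case[0] + counts_case[1]
    c = 2 * counts_control[2] + counts_control[1]
    d = 2 * counts_control[0] + counts_control[1]
    return a, b, c, d


def odds_ratio_2x2(
    a: float,
    b: float,
    c: float,
    d: float,
    correction: str = "haldane",
    *,
    contrast: str = "allele",
    study_id: str = "",
    year: int = 0,
) -> EffectEstimate:
    """Odds ratio ``ad/(bc)`` with Woolf standard error from a 2x2 table.

    When any cell is zero and ``correction="haldane"``, 0.5 is added to all
    four cells (Haldane-Anscombe) and the estimate is flagged ``corrected``.
    """
    cells = [float(a), float(b), float(c), float(d)]
    if any(x < 0 for x in cells):
        raise ValueError("2x2 cells must be non-negative")
    corrected = False
    if any(x == 0 for x in cells):
        if correction == "haldane":
            cells = [x + 0.5 for x in cells]
            corrected = True
        else:
            raise DegenerateTableError("zero cell without continuity correction")
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_) - math.log(b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    if not (math.isfinite(log_or) and math.isfinite(se)):
        raise DegenerateTableError("table too sparse for a finite odds ratio")
    return EffectEstimate(
        log_or=log_or, se=se, contrast=contrast, study_id=study_id, year=year, corrected=corrected
    )


def genotype_ors(
    counts_case: Sequence[int],
    counts_control: Sequence[int],
    correction: str = "haldane",
    *,
    study_id: str = "",
    year: int = 0,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Per-genotype odds ratios against the common-homozygote reference.

    Returns ``(OR1, OR2)``: heterozygote vs common homozygote and rare
    homozygote vs common homozygote.  Continuity correction, when needed, is
    applied to each 2x2 sub-table independently.  The two estimates share the
    reference cell and are therefore positively correlated; downstream
    inference accounts for that by resampling studies rather than by an
    analytic covariance.
    """
    cc, ct = list(counts_case), list(counts_control)
    if cc[0] == 0 and ct[0] == 0:
        raise DegenerateTableError("common-homozygote reference empty in both arms")
    or1 = odds_ratio_2x2(
        cc[1], cc[0], ct[1], ct[0], correction,
        contrast="het-vs-common-hom", study_id=study_id, year=year,
    )
    or2 = odds_ratio_2x2(
        cc[2], cc[0], ct[2], ct[0], correction,
        contrast="rare-hom-vs-common-hom", study_id=study_id, year=year,
    )
    return or1, or2


def _hwe_chi2(n_hom_common: int, n_het: int, n_hom_rare: int) -> float:
    n = n_hom_common + n_het + n_hom_rare
    q = (2 * n_hom_rare + n_het) / (2 * n)  # minor-allele frequency
    p = 1 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_common, n_het, n_hom_rare], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(control_counts: Sequence[int], method: str = "chi2") -> float:
    """Hardy-Weinberg equilibrium p-value for a genotype triple.

    ``chi2``: 1-df goodness-of-fit against the HWE expectation at the observed
    allele frequency (no continuity correction).  ``exact``: full conditional
    enumeration of heterozygote counts given the allele counts, two-sided by
    cumulative probability of tables as extreme or more extreme.

    A monomorphic sample carries no information and returns p = 1 with a
    warning.
    """
    n0, n1, n2 = (int(c) for c in control_counts)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n_minor = 2 * n2 + n1
    n_major = 2 * n0 + n1
    if n_minor == 0 or n_major == 0:
        warnings.warn("monomorphic sample: HWE test undefined, returning p=1")
        return 1.0
    if method == "chi2":
        return _hwe_chi2(n0, n1, n2)
    if method == "exact":
        # Conditional distribution of the heterozygote count h given the
        # allele counts: P(h) proportional to 2^h / (n_common! h! n_rare!),
        # over all h with the parity of the minor-allele count.
        n = n0 + n1 + n2
        hs = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
        n_rare = (n_minor - hs) // 2
        n_common = n - hs - n_rare
        logp = hs * math.log(2.0) - (
            gammaln(n_common + 1) + gammaln(hs + 1) + gammaln(n_rare + 1)
        )
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        p_obs = probs[hs == n1][0]
        return float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    raise ValueError(f"unknown HWE method {method!r}")


def log_or_from_ci(or_value: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log OR, SE) from a reported OR and 95% CI.

    SE = (ln ci_high - ln ci_low) / (2 * 1.95996...), the width of the
    interval on the log scale divided by twice the normal quantile.
    """
    if not 0 < ci_low < or_value < ci_high:
        raise ValueError("need 0 < ci_low < OR < ci_high")
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    return math.log(or_value), se


def effect_from_record(record, prefer: str = "counts", correction: str = "haldane") -> EffectEstimate:
    """Minor-allele effect estimate for a catalogue record.

    ``prefer="counts"`` derives the allele-level OR from genotype counts when
    available, falling back to the reported OR/CI; ``prefer="reported"``
    reverses the preference.
    """
    use_counts = record.has_counts if prefer == "counts" else (
        record.reported_or is None and record.has_counts
    )
    if use_counts:
        a, b, c, d = allele_table_from_genotypes(record.case_counts, record.control_counts)
        return odds_ratio_2x2(
            a, b, c, d, correction, contrast="allele",
            study_id=record.study_id, year=record.year,
        )
    if record.reported_or is not None:
        log_or, se = log_or_from_ci(
            record.reported_or, record.reported_ci_low, record.reported_ci_high
        )
        return EffectEstimate(
            log_or=log_or, se=se, contrast="reported",
            study_id=record.study_id, year=record.year,
        )
    raise ValueError(f"record {record.study_id} has neither counts nor a reported OR")
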