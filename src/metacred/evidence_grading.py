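"""Venice-criteria credibility grading and the FPRP-based upgrade synthesis.

Each significant association receives three letter grades:

* **amount of evidence** — from the total count of test alleles among cases
  and controls: A > 1000, B for 100-1000, C < 100;
* **replication** — from the heterogeneity statistic: A for I^2 < 25%,
  B for I^2 between 25% and 50%, C for I^2 > 50%;
* **protection from bias** — A when no bias is observable (small-study test
  non-significant, sensitivity-stable, and effect magnitude >= 1.15 or
  replicated by GWAS), C when bias is evident or the summary OR is below
  1.15 in magnitude without GWAS replication, B when bias could be present
  (e.g. the small-study test could not be run).

The composite initial grade is strong when all three are A, moderate when
all are A or B, weak when any is C.  An FPRP value below 0.05 then upgrades
the composite by one level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .catalogue import EVIDENCE_GRADES, FPRP_CATEGORIES

__all__ = [
    "CredibilityRecord",
    "NotSignificantError",
    "grade_amount",
    "grade_replication",
    "grade_bias",
    "composite_venice",
    "apply_fprp_upgrade",
    "grade_association",
    "grade_from_summary",
]

_ORDER = {g: i for i, g in enumerate(EVIDENCE_GRADES)}  # weak < moderate < strong


class NotSignificantError(ValueError):
    """Grading was requested for an association that is not significant."""


@dataclass(frozen=True)
class CredibilityRecord:
    amount_grade: str
    replication_grade: str
    bias_grade: str
    venice_initial: str
    fprp_category: str
    final_grade: str
    rationale: tuple[str, ...] = ()


def grade_amount(evidence_amount: int) -> str:
    """Amount-of-evidence grade from the test-allele total."""
    if evidence_amount < 0:
        raise ValueError("evidence amount cannot be negative")
    if evidence_amount > 1000:
        return "A"
    if evidence_amount >= 100:
        return "B"
    return "C"


def grade_replication(i_squared_pct: float) -> str:
    """Replication grade from between-study heterogeneity (I^2, percent)."""
    if i_squared_pct < 0:
        raise ValueError("I^2 cannot be negative")
    if i_squared_pct < 25:
        return "A"
    if i_squared_pct <= 50:
        return "B"
    return "C"


def grade_bias(
    or_pooled: float,
    gwas_replicated: bool = False,
    harbord_p: Optional[float] = None,
    sensitivity_stable: bool = True,
    harbord_threshold: float = 0.10,
) -> tuple[str, list[str]]:
    """Protection-from-bias grade with the list of rules that fired.

    The OR-magnitude rule is symmetric: max(OR, 1/OR) < 1.15 counts as a
    small effect, so protective associations are treated like risk ones.
    """
    if or_pooled <= 0:
        raise ValueError("odds ratio must be positive")
    fired: list[str] = []
    magnitude = max(or_pooled, 1.0 / or_pooled)
    small_effect = magnitude < 1.15
    harbord_sig = harbord_p is not None and harbord_p < harbord_threshold

    if harbord_sig:
        fired.append("bias:harbord-significant")
    if not sensitivity_stable:
        fired.append("bias:sensitivity-unstable")
    if small_effect and not gwas_replicated:
        fired.append("bias:small-or-no-gwas")
    if fired:
        return "C", fired

    if small_effect and gwas_replicated:
        fired.append("bias:small-or-gwas-rescue")
    if harbord_p is None:
        fired.append("bias:harbord-unavailable")
        return "B", fired
    fired.append("bias:no-observable-bias")
    return "A", fired


def composite_venice(amount: str, replication: str, bias: str) -> str:
    """Composite Venice grade: strong iff AAA, moderate iff all in {A,B},
    weak iff any C."""
    grades = (amount, replication, bias)
    if any(g not in {"A", "B", "C"} for g in grades):
        raise ValueError(f"grades must be A, B or C, got {grades}")
    if any(g == "C" for g in grades):
        return "weak"
    if all(g == "A" for g in grades):
        return "strong"
    return "moderate"


def apply_fprp_upgrade(venice_initial: str, fprp_category: str) -> str:
    """One-level upgrade of the composite grade when FPRP < 0.05."""
    if venice_initial not in EVIDENCE_GRADES:
        raise ValueError(f"unknown grade {venice_initial!r}")
    if fprp_category not in FPRP_CATEGORIES:
        raise ValueError(f"unknown FPRP category {fprp_category!r}")
    if fprp_category == "<0.05":
        return EVIDENCE_GRADES[min(_ORDER[venice_initial] + 1, len(EVIDENCE_GRADES) - 1)]
    return venice_initial


def grade_association(
    meta,
    fprp_result,
    harbord=None,
    sensitivity=None,
    gwas_replicated: bool = False,
    harbord_threshold: float = 0.10,
) -> CredibilityRecord:
    """Full grading chain for one pooled association.

    Parameters
    ----------
    meta : MetaResult
        Must be nominally significant (p < 0.05); grading a non-significant
        association is refused, since credibility grades only apply to
        identified associations.
    fprp_result : FprpResult
    harbord : HarbordResult, optional
        Treated as unavailable when absent or skipped.
    sensitivity : SensitivityReport, optional
        Treated as stable when absent (no counts to re-pool).
    """
    if meta.p_value >= 0.05:
        raise NotSignificantError(
            f"association is not significant (p = {meta.p_value:.3g}); grading refused"
        )
    rationale: list[str] = []
    amount = grade_amount(meta.evidence_amount)
    rationale.append(f"amount:{amount}:n={meta.evidence_amount}")
    replication = grade_replication(meta.i_squared_pct)
    rationale.append(f"replication:{replication}:i2={meta.i_squared_pct:.1f}")
    harbord_p = None
    if harbord is not None and not harbord.skipped:
        harbord_p = harbord.p_value
    stable = sensitivity.stable if sensitivity is not None else True
    bias, bias_rules = grade_bias(
        meta.or_pooled, gwas_replicated, harbord_p, stable, harbord_threshold
    )
    rationale.extend(bias_rules)
    initial = composite_venice(amount, replication, bias)
    final = apply_fprp_upgrade(initial, fprp_result.category)
    if final != initial:
        rationale.append("fprp:upgrade")
    return CredibilityRecord(
        amount_grade=amount,
        replication_grade=replication,
        bias_grade=bias,
        venice_initial=initial,
        fprp_category=fprp_result.category,
        final_grade=final,
        rationale=tuple(rationale),
    )


def grade_from_summary(summary) -> CredibilityRecord:
    """Grading chain for a published association summary.

    The replication grade is re-derived from the printed I^2; the initial
    Venice grade and FPRP category are taken as printed (their amount and
    bias inputs are not recoverable from a summary table), and the FPRP
    upgrade is applied to produce the final grade.
    """
    if not summary.significant:
        raise NotSignificantError(
            f"{summary.variant}/{summary.cancer} is not significant; grading refused"
        )
    replication = grade_replication(summary.i_squared_pct)
    final = apply_fprp_upgrade(summary.venice_initial, summary.fprp_category)
    return CredibilityRecord(
        amount_grade="",
        replication_grade=replication,
        bias_grade="",
        venice_initial=summary.venice_initial,
        fprp_category=summary.fprp_category,
        final_grade=final,
        rationale=(
            f"replication:{replication}:i2={summary.i_squared_pct:.1f}",
            "venice:as-printed",
            "fprp:upgrade" if final != summary.venice_initial else "fprp:no-upgrade",
        ),
    )
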