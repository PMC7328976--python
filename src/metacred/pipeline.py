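"""End-to-end orchestration: catalogue in, graded synopsis out.

Two entry modes mirror how evidence synopses are actually assembled:

* **count mode** (:func:`run_synopsis`) — full pipeline from per-study
  genotype counts: per-study effects, heterogeneity, model selection,
  pooling, sensitivity suite, Harbord small-study test, FPRP, Venice
  grading and the FPRP upgrade;
* **summary mode** (:func:`grade_summaries`) — published association
  summaries in (OR/CI/p/I^2, initial grade, FPRP category), final grades
  out; used when the source studies' raw counts are unavailable.

Associations are graded at nominal significance (p < 0.05); no
multiple-testing correction is applied, and the output header says so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__ as _pkg_version
from .catalogue import (
    AssociationSummary,
    StudyRecord,
    read_catalogue,
    write_results,
)
from .evidence_grading import CredibilityRecord, grade_association, grade_from_summary
from .fprp import (
    DEFAULT_HEADLINE_PRIOR,
    DEFAULT_PRIORS,
    DEFAULT_TARGET_OR,
    FprpResult,
    fprp_for_association,
)
from .meta_engine import (
    MetaResult,
    ModelPolicy,
    SensitivityReport,
    evidence_amount,
    forest_table,
    pool,
    sensitivity_suite,
)
from .model_free import GeneticModelEstimate, model_free_analysis
from .small_study_bias import HarbordResult, harbord_test
from .study_effects import allele_table_from_genotypes, effect_from_record

logger = logging.getLogger("metacred")

__all__ = ["RunConfig", "AssociationResult", "run_synopsis", "grade_summaries"]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run configuration; every default is documented in
    the methods note and recorded in the run manifest."""

    # model selection: random effects when I^2 > i2_threshold or Q-p < qp_threshold
    i2_threshold: float = 50.0
    qp_threshold: float = 0.10
    hwe_threshold: float = 0.05
    correction: str = "haldane"
    prefer: str = "counts"  # per-study estimate preference: counts | reported
    evidence_mode: str = "alleles"
    fprp_priors: tuple[float, ...] = DEFAULT_PRIORS
    fprp_target_or: float = DEFAULT_TARGET_OR
    fprp_headline_prior: float = DEFAULT_HEADLINE_PRIOR
    harbord_min_k: int = 3
    harbord_threshold: float = 0.10
    run_model_free: bool = True
    n_boot: int = 2000
    lambda_floor: float = 0.10
    seed: int = 0

    @property
    def policy(self) -> ModelPolicy:
        return ModelPolicy(i2_threshold=self.i2_threshold, qp_threshold=self.qp_threshold)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = json.load(fh)
        if "fprp_priors" in raw:
            raw["fprp_priors"] = tuple(raw["fprp_priors"])
        return cls(**raw)


@dataclass
class AssociationResult:
    variant: str
    cancer: str
    meta: MetaResult
    sensitivity: Optional[SensitivityReport]
    harbord: Optional[HarbordResult]
    fprp: Optional[FprpResult]
    credibility: Optional[CredibilityRecord]
    model_free: Optional[GeneticModelEstimate]

    @property
    def significant(self) -> bool:
        return self.meta.p_value < 0.05

    def to_row(self) -> dict:
        row = {
            "variant": self.variant,
            "cancer": self.cancer,
            "k": self.meta.k,
            "or": round(self.meta.or_pooled, 4),
            "ci_low": round(self.meta.ci_low, 4),
            "ci_high": round(self.meta.ci_high, 4),
            "p_value": self.meta.p_value,
            "model": self.meta.model,
            "q_stat": round(self.meta.q_stat, 4),
            "q_p": round(self.meta.q_p, 4),
            "i_squared_pct": round(self.meta.i_squared_pct, 2),
            "tau2": round(self.meta.tau2, 6),
            "evidence_amount": self.meta.evidence_amount,
            "significant": int(self.significant),
            "harbord_p": (
                "" if self.harbord is None or self.harbord.skipped
                else round(self.harbord.p_value, 4)
            ),
            "sensitivity_stable": (
                "" if self.sensitivity is None or self.sensitivity.skipped
                else int(self.sensitivity.stable)
            ),
        }
        if self.credibility is not None:
            c = self.credibility
            row.update(
                amount_grade=c.amount_grade,
                replication_grade=c.replication_grade,
                bias_grade=c.bias_grade,
                venice_initial=c.venice_initial,
                fprp_category=c.fprp_category,
                final_grade=c.final_grade,
                rationale=";".join(c.rationale),
            )
        else:
            row.update(
                amount_grade="", replication_grade="", bias_grade="",
                venice_initial="", fprp_category="", final_grade="", rationale="",
            )
        if self.model_free is not None and self.model_free.lambda_ is not None:
            row["lambda"] = round(self.model_free.lambda_, 4)
            row["inheritance_model"] = self.model_free.model_class
        else:
            row["lambda"] = ""
            row["inheritance_model"] = ""
        return row


def _analyse_group(
    variant: str, cancer: str, records: list[StudyRecord], config: RunConfig
) -> AssociationResult:
    effects = [effect_from_record(r, prefer=config.prefer, correction=config.correction)
               for r in records]
    amount = evidence_amount(records, mode=config.evidence_mode)
    meta = pool(effects, config.policy, evidence=amount)

    sens = sensitivity_suite(
        records, config.policy, hwe_threshold=config.hwe_threshold, prefer=config.prefer
    ) if len(records) >= 2 else None

    tables = [allele_table_from_genotypes(r.case_counts, r.control_counts)
              for r in records if r.has_counts]
    n_excluded = len(records) - len(tables)
    harbord = harbord_test(tables, min_k=config.harbord_min_k, n_excluded=n_excluded)

    fprp = None
    credibility = None
    mf = None
    if meta.p_value < 0.05:
        fprp = fprp_for_association(
            meta.p_value,
            meta.pooled_se,
            pooled_or=meta.or_pooled,
            priors=config.fprp_priors,
            target_or=config.fprp_target_or,
            headline_prior=config.fprp_headline_prior,
        )
        gwas = any(r.gwas_replicated for r in records)
        credibility = grade_association(
            meta, fprp, harbord=harbord, sensitivity=sens,
            gwas_replicated=gwas, harbord_threshold=config.harbord_threshold,
        )
        if config.run_model_free and len(tables) >= 2:
            try:
                mf = model_free_analysis(
                    records, n_boot=config.n_boot, seed=config.seed,
                    floor=config.lambda_floor, correction=config.correction,
                )
            except ValueError as exc:
                logger.info("model-free analysis skipped for %s/%s: %s", variant, cancer, exc)
    return AssociationResult(
        variant=variant, cancer=cancer, meta=meta, sensitivity=sens,
        harbord=harbord, fprp=fprp, credibility=credibility, model_free=mf,
    )


def run_synopsis(
    catalogue: str | Path | Sequence[StudyRecord],
    config: RunConfig = RunConfig(),
    out_dir: Optional[str | Path] = None,
) -> list[AssociationResult]:
    """Run the full count-mode pipeline over a catalogue.

    Groups records by (variant, cancer), analyses each group, and (when
    ``out_dir`` is given) writes the results table, run manifest and
    per-association forest tables.
    """
    checksum = None
    if isinstance(catalogue, (str, Path)):
        path = Path(catalogue)
        checksum = hashlib.sha256(path.read_bytes()).hexdigest()
        load = read_catalogue(path)
        if load.rejects:
            logger.warning("%d catalogue rows rejected", len(load.rejects))
        records = load.records
    else:
        records = list(catalogue)

    groups: dict[tuple[str, str], list[StudyRecord]] = {}
    for r in records:
        groups.setdefault((r.variant, r.cancer), []).append(r)
    if not groups:
        logger.warning("empty catalogue: nothing to analyse")

    results = [
        _analyse_group(variant, cancer, group, config)
        for (variant, cancer), group in sorted(groups.items())
    ]

    if out_dir is not None:
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "version": _pkg_version,
            "input_sha256": checksum,
            "n_records": len(records),
            "n_associations": len(results),
            "note": "associations graded at nominal p < 0.05; no multiplicity correction",
        }
        forest = {}
        for (variant, cancer), group in sorted(groups.items()):
            forest[f"{variant}_{cancer}"] = forest_table(group, config.policy, config.prefer)
        write_results([r.to_row() for r in results], out_dir, manifest, forest)
    return results


def grade_summaries(
    summaries: Sequence[AssociationSummary],
) -> list[tuple[AssociationSummary, Optional[CredibilityRecord]]]:
    """Summary-mode grading: apply the grading chain to published summaries.

    Non-significant entries pass through ungraded (None)."""
    out = []
    for s in summaries:
        out.append((s, grade_from_summary(s) if s.significant else None))
    return out
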