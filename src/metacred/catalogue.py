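"""Study-level catalogue: data model, validated I/O, and the encoded 8q24 association table.

The catalogue is the unit of input for the whole synopsis pipeline: one row per
study x variant x cancer, carrying either case/control genotype counts or, when
a source publication reported only a summary estimate, the odds ratio with its
95% confidence interval.

The packaged fixture (``load_inpaper_fixture``) transcribes the published
8q24/cancer association table: pooled OR, CI and p for each of the 23
nominally significant associations, their I^2 and heterogeneity p, the false
positive report probability (FPRP) category, the initial Venice grade and the
final cumulative-evidence grade, plus the associations reported as
non-significant.  These printed summaries are encoded exactly as published and
are never re-derived here, because the underlying per-study data of the 103
source articles are not part of this package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CANCERS",
    "ETHNICITIES",
    "FPRP_CATEGORIES",
    "EVIDENCE_GRADES",
    "CATALOGUE_COLUMNS",
    "StudyRecord",
    "AssociationSummary",
    "RejectedRow",
    "CatalogueLoad",
    "SchemaError",
    "read_catalogue",
    "write_catalogue",
    "load_inpaper_fixture",
    "write_results",
]

CANCERS = frozenset(
    {"prostate", "colorectal", "thyroid", "breast", "bladder", "stomach", "glioma", "other"}
)
ETHNICITIES = frozenset({"African", "Asian", "Caucasian", "other"})
FPRP_CATEGORIES = ("<0.05", "0.05–0.20", ">0.20")
EVIDENCE_GRADES = ("weak", "moderate", "strong")

#: Column order of the tab-separated catalogue format.
CATALOGUE_COLUMNS = [
    "study_id",
    "author",
    "year",
    "cancer",
    "variant",
    "ethnicity",
    "design",
    "case_hom_common",
    "case_het",
    "case_hom_rare",
    "ctrl_hom_common",
    "ctrl_het",
    "ctrl_hom_rare",
    "reported_or",
    "reported_ci_low",
    "reported_ci_high",
    "gwas_replicated",
]


class SchemaError(ValueError):
    """The catalogue file does not match the documented column schema."""


@dataclass
class StudyRecord:
    """One study's contribution to one variant-cancer association.

    Genotype counts are oriented ``(common-homozygote, heterozygote,
    rare-homozygote)`` with the minor allele as the test allele.  When counts
    were not published, ``reported_or`` with its CI stands in for them.
    Microsatellite alleles (e.g. the DG8S737 "-8" allele) are represented as
    biallelic carrier/non-carrier counts.
    """

    study_id: str
    author: str
    year: int
    cancer: str
    variant: str
    ethnicity: str
    design: str = "case-control"
    case_counts: Optional[tuple[int, int, int]] = None
    control_counts: Optional[tuple[int, int, int]] = None
    reported_or: Optional[float] = None
    reported_ci_low: Optional[float] = None
    reported_ci_high: Optional[float] = None
    gwas_replicated: bool = False
    hwe_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cancer not in CANCERS:
            raise ValueError(f"unknown cancer label {self.cancer!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity label {self.ethnicity!r}")
        if not 1990 <= int(self.year) <= 2100:
            raise ValueError(f"implausible publication year {self.year}")
        self.year = int(self.year)
        for arm, counts in (("case", self.case_counts), ("control", self.control_counts)):
            if counts is not None:
                counts = tuple(int(c) for c in counts)
                if len(counts) != 3 or any(c < 0 for c in counts):
                    raise ValueError(f"{arm} genotype counts must be 3 non-negative integers")
        if self.case_counts is not None:
            self.case_counts = tuple(int(c) for c in self.case_counts)
        if self.control_counts is not None:
            self.control_counts = tuple(int(c) for c in self.control_counts)
        if (self.case_counts is None) != (self.control_counts is None):
            raise ValueError("genotype counts must be present for both arms or neither")
        has_reported = self.reported_or is not None
        if not self.has_counts and not has_reported:
            raise ValueError("record needs genotype counts or a reported OR")
        if has_reported:
            if self.reported_ci_low is None or self.reported_ci_high is None:
                raise ValueError("reported OR requires both CI bounds")
            if not (0 < self.reported_ci_low < self.reported_or < self.reported_ci_high):
                raise ValueError(
                    "reported CI must satisfy 0 < ci_low < OR < ci_high, got "
                    f"({self.reported_ci_low}, {self.reported_or}, {self.reported_ci_high})"
                )
        if self.hwe_p is not None and not 0.0 <= self.hwe_p <= 1.0:
            raise ValueError("hwe_p must lie in [0, 1]")

    @property
    def has_counts(self) -> bool:
        return self.case_counts is not None and self.control_counts is not None


@dataclass(frozen=True)
class AssociationSummary:
    """A published variant-cancer association summary.

    For non-significant associations the source table prints no numbers
    ("data not shown"), so all numeric fields are optional and ``significant``
    carries the distinction.
    """

    variant: str
    cancer: str
    significant: bool
    or_pooled: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    i_squared_pct: Optional[float] = None
    het_p: Optional[float] = None
    fprp_category: Optional[str] = None
    venice_initial: Optional[str] = None
    final_grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cancer not in CANCERS:
            raise ValueError(f"unknown cancer label {self.cancer!r}")
        if self.significant:
            if not (0 < self.ci_low < self.or_pooled < self.ci_high):
                raise ValueError("CI must bracket the pooled OR")
            if not 0 < self.p_value <= 1:
                raise ValueError("p-value out of range")
            if self.i_squared_pct < 0:
                raise ValueError("I^2 cannot be negative")
            if self.fprp_category not in FPRP_CATEGORIES:
                raise ValueError(f"unknown FPRP category {self.fprp_category!r}")
            for grade in (self.venice_initial, self.final_grade):
                if grade not in EVIDENCE_GRADES:
                    raise ValueError(f"unknown evidence grade {grade!r}")


@dataclass(frozen=True)
class RejectedRow:
    """A catalogue row that failed validation, with its 0-based data row index."""

    row_index: int
    reason: str


@dataclass
class CatalogueLoad:
    records: list[StudyRecord]
    rejects: list[RejectedRow]


_INT_COLS = [
    "case_hom_common", "case_het", "case_hom_rare",
    "ctrl_hom_common", "ctrl_het", "ctrl_hom_rare",
]


def _parse_row(row: Mapping[str, str], index: int) -> StudyRecord:
    def opt_float(key: str) -> Optional[float]:
        raw = (row.get(key) or "").strip()
        return float(raw) if raw else None

    counts_raw = [(row.get(c) or "").strip() for c in _INT_COLS]
    if any(counts_raw):
        if not all(counts_raw):
            raise ValueError("genotype counts are partially filled")
        counts = [int(float(v)) for v in counts_raw]
        case_counts = tuple(counts[:3])
        control_counts = tuple(counts[3:])
    else:
        case_counts = control_counts = None
    gwas = (row.get("gwas_replicated") or "").strip().lower() in {"1", "true", "yes"}
    return StudyRecord(
        study_id=row["study_id"].strip(),
        author=row["author"].strip(),
        year=int(float(row["year"])),
        cancer=row["cancer"].strip(),
        variant=row["variant"].strip(),
        ethnicity=row["ethnicity"].strip(),
        design=(row.get("design") or "case-control").strip(),
        case_counts=case_counts,
        control_counts=control_counts,
        reported_or=opt_float("reported_or"),
        reported_ci_low=opt_float("reported_ci_low"),
        reported_ci_high=opt_float("reported_ci_high"),
        gwas_replicated=gwas,
    )


def read_catalogue(path: str | Path, dialect: str = "tab") -> CatalogueLoad:
    """Read a study catalogue, validating every row.

    Malformed rows are collected into the reject report rather than silently
    dropped; a missing mandatory column aborts with :class:`SchemaError`.

    Parameters
    ----------
    path
        Delimited text file following :data:`CATALOGUE_COLUMNS`.
    dialect
        ``"tab"`` (default) or ``"comma"``.
    """
    sep = "\t" if dialect == "tab" else ","
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        header = reader.fieldnames or []
        missing = [c for c in CATALOGUE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"catalogue is missing mandatory column(s): {', '.join(missing)}")
        records: list[StudyRecord] = []
        rejects: list[RejectedRow] = []
        for i, row in enumerate(reader):
            try:
                records.append(_parse_row(row, i))
            except (ValueError, KeyError) as exc:
                rejects.append(RejectedRow(row_index=i, reason=str(exc)))
    return CatalogueLoad(records=records, rejects=rejects)


def write_catalogue(records: Iterable[StudyRecord], path: str | Path, dialect: str = "tab") -> None:
    """Write records in the catalogue format; inverse of :func:`read_catalogue`."""
    sep = "\t" if dialect == "tab" else ","
    rows = []
    for r in records:
        case = r.case_counts or ("", "", "")
        ctrl = r.control_counts or ("", "", "")
        rows.append(
            {
                "study_id": r.study_id,
                "author": r.author,
                "year": r.year,
                "cancer": r.cancer,
                "variant": r.variant,
                "ethnicity": r.ethnicity,
                "design": r.design,
                "case_hom_common": case[0],
                "case_het": case[1],
                "case_hom_rare": case[2],
                "ctrl_hom_common": ctrl[0],
                "ctrl_het": ctrl[1],
                "ctrl_hom_rare": ctrl[2],
                "reported_or": "" if r.reported_or is None else repr(r.reported_or),
                "reported_ci_low": "" if r.reported_ci_low is None else repr(r.reported_ci_low),
                "reported_ci_high": "" if r.reported_ci_high is None else repr(r.reported_ci_high),
                "gwas_replicated": int(r.gwas_replicated),
            }
        )
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CATALOGUE_COLUMNS, delimiter=sep)
        writer.writeheader()
        writer.writerows(rows)


def load_inpaper_fixture() -> list[AssociationSummary]:
    """Load the packaged 8q24 association table.

    Returns the 23 significant associations (with printed OR/CI/p, I^2,
    heterogeneity p, FPRP category and grades) followed by the associations
    named as non-significant, flagged ``significant=False``.
    """
    ref = resources.files("metacred").joinpath("data/8q24_associations.tsv")
    out: list[AssociationSummary] = []
    with ref.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            significant = row["significant"].strip() == "1"

            def num(key: str) -> Optional[float]:
                raw = (row.get(key) or "").strip()
                return float(raw) if raw else None

            out.append(
                AssociationSummary(
                    variant=row["variant"],
                    cancer=row["cancer"],
                    significant=significant,
                    or_pooled=num("or_pooled"),
                    ci_low=num("ci_low"),
                    ci_high=num("ci_high"),
                    p_value=num("p_value"),
                    i_squared_pct=num("i_squared_pct"),
                    het_p=num("het_p"),
                    fprp_category=(row.get("fprp_category") or None) if significant else None,
                    venice_initial=(row.get("venice_initial") or None) if significant else None,
                    final_grade=(row.get("final_grade") or None) if significant else None,
                )
            )
    return out


def write_results(
    rows: Sequence[Mapping],
    out_dir: str | Path,
    manifest: Optional[Mapping] = None,
    forest_tables: Optional[Mapping[str, pd.DataFrame]] = None,
) -> dict[str, Path]:
    """Write the graded results table, run manifest, and forest-plot tables.

    Parameters
    ----------
    rows
        One mapping per association (the graded synopsis row).
    manifest
        Run configuration, seed and version; serialized as JSON.
    forest_tables
        Per-association study-level effect tables keyed by an association
        label; each becomes ``forest/<label>.tsv``.

    Returns the mapping from artifact name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    results_path = out_dir / "results.tsv"
    pd.DataFrame(list(rows)).to_csv(results_path, sep="\t", index=False)
    written["results"] = results_path

    manifest_path = out_dir / "manifest.json"
    with manifest_path.open("w", encoding="utf-8") as fh:
        json.dump(dict(manifest or {}), fh, indent=2, sort_keys=True, default=str)
    written["manifest"] = manifest_path

    if forest_tables:
        forest_dir = out_dir / "forest"
        forest_dir.mkdir(exist_ok=True)
        for label, table in forest_tables.items():
            safe = "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in label)
            p = forest_dir / f"{safe}.tsv"
            table.to_csv(p, sep="\t", index=False)
            written[f"forest/{safe}"] = p
    return written
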