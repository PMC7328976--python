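"""Synthetic case-control genotype catalogues with known truth.

The generator emulates the data-generating structure the pooled analysis
assumes: control genotypes drawn from Hardy-Weinberg proportions at a given
minor-allele frequency; per-genotype disease odds (1, OR1, OR2) with
OR1 = OR2^lambda; between-study heterogeneity as a normal random effect with
variance tau^2 on the log-OR2 scale; and an optional publication-selection
mechanism retaining each study with a probability that decreases in its
p-value.  Case genotype probabilities are obtained by odds-weighting the
control distribution and renormalizing, so the generating odds ratios are
exactly the estimands of the downstream estimators (under a multiplicative
model, lambda = 0.5, the allele-level OR equals OR2^0.5 exactly).

Every study is generated from its own deterministic substream,
``default_rng([seed, study_index])``, so a catalogue can be extended without
reshuffling earlier studies.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import stats

from .catalogue import StudyRecord

__all__ = [
    "SimulationConfig",
    "simulate_study",
    "simulate_catalogue",
    "default_selection_rule",
    "control_genotype_probs",
    "case_genotype_probs",
]

_ETHNICITY_CYCLE = ("Caucasian", "Asian", "African", "other")


def default_selection_rule(p_value: float) -> float:
    """Publish with probability 1 when p < 0.05, else 0.25."""
    return 1.0 if p_value < 0.05 else 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a synthetic study catalogue.

    ``n_cases``/``n_controls`` are either a fixed per-study count or an
    inclusive ``(low, high)`` range sampled uniformly per study.
    """

    n_studies: int = 10
    maf: float = 0.3
    or2: float = 1.5
    lambda_true: float = 0.5
    tau2: float = 0.0
    n_cases: Union[int, tuple[int, int]] = 1000
    n_controls: Union[int, tuple[int, int]] = 1000
    hwe_in_controls: bool = True
    #: inbreeding coefficient used to distort control genotypes when
    #: hwe_in_controls is False
    inbreeding_f: float = 0.15
    selection: Optional[Callable[[float], float]] = None
    seed: int = 0
    cancer: str = "prostate"
    variant: str = "rs0000000"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.or2 <= 0:
            raise ValueError("or2 must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if isinstance(v, int):
                if v < 1:
                    raise ValueError(f"{name} must be >= 1")
            else:
                lo, hi = v
                if not (1 <= lo <= hi):
                    raise ValueError(f"{name} range must satisfy 1 <= low <= high")


def control_genotype_probs(maf: float, f: float = 0.0) -> np.ndarray:
    """Genotype probabilities (common-hom, het, rare-hom) for the control
    population; ``f`` is an inbreeding coefficient (0 gives exact HWE)."""
    q = maf
    p = 1 - q
    probs = np.array(
        [p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q], dtype=float
    )
    return probs / probs.sum()


def case_genotype_probs(control_probs: np.ndarray, log_or1: float, log_or2: float) -> np.ndarray:
    """Case genotype probabilities: odds-weight the control distribution by
    (1, e^log_or1, e^log_or2) and renormalize."""
    weights = np.array([1.0, math.exp(log_or1), math.exp(log_or2)])
    probs = control_probs * weights
    return probs / probs.sum()


def _draw_n(rng: np.random.Generator, spec: Union[int, tuple[int, int]]) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_study(config: SimulationConfig, study_index: int) -> StudyRecord:
    """Generate one study's genotype counts; deterministic in
    (config.seed, study_index)."""
    rng = np.random.default_rng([config.seed, study_index])
    n_cases = _draw_n(rng, config.n_cases)
    n_controls = _draw_n(rng, config.n_controls)
    log_or2 = rng.normal(math.log(config.or2), math.sqrt(config.tau2))
    log_or1 = config.lambda_true * log_or2
    f = 0.0 if config.hwe_in_controls else config.inbreeding_f
    g_ctrl = control_genotype_probs(config.maf, f)
    g_case = case_genotype_probs(g_ctrl, log_or1, log_or2)
    case_counts = tuple(int(c) for c in rng.multinomial(n_cases, g_case))
    control_counts = tuple(int(c) for c in rng.multinomial(n_controls, g_ctrl))
    return StudyRecord(
        study_id=f"S{study_index:04d}",
        author=f"sim{study_index:04d}",
        year=2000 + study_index % 18,
        cancer=config.cancer,
        variant=config.variant,
        ethnicity=_ETHNICITY_CYCLE[study_index % len(_ETHNICITY_CYCLE)],
        case_counts=case_counts,
        control_counts=control_counts,
    )


def _allele_p_value(record: StudyRecord) -> float:
    from .study_effects import allele_table_from_genotypes, odds_ratio_2x2

    a, b, c, d = allele_table_from_genotypes(record.case_counts, record.control_counts)
    e = odds_ratio_2x2(a, b, c, d)
    return float(2 * stats.norm.sf(abs(e.log_or / e.se)))


def simulate_catalogue(config: SimulationConfig) -> tuple[list[StudyRecord], dict]:
    """Generate a catalogue of independent studies plus a truth sidecar.

    With a ``selection`` rule, each study is retained with probability
    ``selection(p)`` evaluated at its allele-OR p-value (the retention draw
    uses a dedicated substream, ``default_rng([seed, study_index, 1])``, so
    the genotype draws are unchanged by toggling selection).
    """
    records: list[StudyRecord] = []
    for i in range(config.n_studies):
        record = simulate_study(config, i)
        if config.selection is not None:
            p = _allele_p_value(record)
            keep_prob = config.selection(p)
            keep_rng = np.random.default_rng([config.seed, i, 1])
            if keep_rng.random() >= keep_prob:
                continue
        records.append(record)
    if not records:
        raise ValueError("publication selection removed every study")
    truth = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k != "selection"
    }
    truth["selection_active"] = config.selection is not None
    truth["log_or2_true"] = math.log(config.or2)
    truth["log_or1_true"] = config.lambda_true * math.log(config.or2)
    truth["n_retained"] = len(records)
    return records, truth
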