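"""Validation and secondary analyses.

Covers: AUC of deficiency scores predicting TP53 mutation status
(Mann-Whitney concordance with tie handling), the confidence and cohort
inclusion filters, the two-group drug-sensitivity t-test on Drug Activity
Area, and bookkeeping summaries of per-cancer-type mutation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    CohortRecord,
    DrugResponse,
    MutationStatus,
    ValidationError,
    align_samples,
)
from .survival_stats import GroupSplit

logger = logging.getLogger(__name__)

AUC_CONFIDENCE_THRESHOLD = 0.60
MIN_DRUG_RESPONSES = 10


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"auc outside [0,1]: {self.auc}")
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValidationError("AUC undefined with an empty class")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_low: float
    mean_high: float
    n_low: int
    n_high: int


def auc_vs_mutation(scores, status: MutationStatus) -> RocResult:
    """AUC of a continuous score predicting binary mutation status.

    Mann-Whitney concordance: (concordant pairs + 0.5 * tied pairs) /
    (n_pos * n_neg), where a pair is one mutant vs one wild-type sample
    and concordant means the mutant scores higher.
    """
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    s, status = align_samples(s.astype(float), status)
    y = status.status.to_numpy()
    x = s.to_numpy(dtype=float)
    pos = x[y == 1]
    neg = x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both mutant and wild-type samples required for AUC")
    # U statistic via midranks handles ties exactly
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))
    return RocResult(auc=float(auc), n_pos=len(pos), n_neg=len(neg))


def confident_signature_filter(
    roc: RocResult, threshold: float = AUC_CONFIDENCE_THRESHOLD
) -> bool:
    """True iff the score captures mutation status confidently: AUC
    strictly above the threshold (default 0.60)."""
    return roc.auc > threshold


def drug_sensitivity_test(split: GroupSplit, response: DrugResponse) -> TTestResult:
    """Two-sided equal-variance Student's t-test on Drug Activity Area
    between the low- and high-deficiency groups of a median split.

    Applied only when at least 10 responses exist after alignment (fewer
    are skipped with a warning by the caller); each group needs >=2.
    """
    labels, area = align_samples(split.labels, response.activity_area)
    if len(area) < MIN_DRUG_RESPONSES:
        raise ValidationError(
            f"only {len(area)} responses; need >= {MIN_DRUG_RESPONSES}"
        )
    low = area[labels == "low"].to_numpy(dtype=float)
    high = area[labels == "high"].to_numpy(dtype=float)
    if len(low) < 2 or len(high) < 2:
        raise ValidationError("each group needs >=2 responses for a t-test")
    t, p = stats.ttest_ind(low, high, equal_var=True)
    return TTestResult(
        t=float(t),
        p=float(p),
        mean_low=float(low.mean()),
        mean_high=float(high.mean()),
        n_low=len(low),
        n_high=len(high),
    )


def cohort_inclusion_filter(record: CohortRecord) -> bool:
    """Cancer-type inclusion rule: at least 20 mutant patients and at
    least a 10% mutation rate (both bounds inclusive)."""
    rate = 100.0 * record.n_mutant / record.n_samples
    return record.n_mutant >= 20 and rate >= 10.0


def dataset_inclusion_filter(n_samples: int, mortality_rate: float) -> bool:
    """Expression-dataset inclusion rule for the survival meta-analysis:
    strictly more than 40 samples and strictly over a 20% mortality rate."""
    if n_samples < 0 or not 0.0 <= mortality_rate <= 1.0:
        raise ValidationError("need n_samples >= 0 and mortality_rate in [0,1]")
    return n_samples > 40 and mortality_rate > 0.20


@dataclass(frozen=True)
class CohortSummary:
    records: list[CohortRecord]
    total_mutant: int
    total_samples: int
    overall_pct_mutant: int  # rounded to integer percent


def cohort_summary(status_by_type: dict[str, MutationStatus]) -> CohortSummary:
    """Per-cancer-type mutant/wild-type counts plus overall totals.

    Per-type percentages are rounded to 1 decimal; the overall mutant
    percentage to the nearest integer.
    """
    if not status_by_type:
        raise ValidationError("no cohorts supplied")
    records = []
    for label in status_by_type:
        st = status_by_type[label].status
        n = len(st)
        n_mut = int(st.sum())
        records.append(
            CohortRecord(
                cancer_type=label,
                n_samples=n,
                n_mutant=n_mut,
                n_wildtype=n - n_mut,
                pct_mutant=round(100.0 * n_mut / n, 1),
            )
        )
    return summarize_records(records)


def summarize_records(records: list[CohortRecord]) -> CohortSummary:
    """Totals over already-counted cohort records (integer arithmetic)."""
    if not records:
        raise ValidationError("no cohort records supplied")
    total_mut = sum(r.n_mutant for r in records)
    total_n = sum(r.n_samples for r in records)
    return CohortSummary(
        records=list(records),
        total_mutant=total_mut,
        total_samples=total_n,
        overall_pct_mutant=int(round(100.0 * total_mut / total_n)),
    )
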