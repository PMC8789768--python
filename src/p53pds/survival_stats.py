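"""Prognostic evaluation: group splits, log-rank tests, univariate Cox
regression and weighted-Stouffer meta-analysis.

Log-rank, Cox (Efron tie handling) and Kaplan-Meier estimation are
delegated to ``lifelines``; the splits and the meta combination are defined
here. The meta z combines per-dataset Cox z-scores with dataset sample
sizes as weights: ``meta_z = sum(n_i z_i) / sqrt(sum(n_i^2))``, with a
two-sided p from the standard normal and the direction (sign) reported
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io_core import SurvivalTable, ValidationError, align_samples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSplit:
    """Per-sample low/high labels with the rule that produced them."""

    labels: pd.Series  # index = sample ids, values in {"low", "high"}
    cutoff_rule: str  # "fraction" or "median"
    q: float | None = None

    def __post_init__(self) -> None:
        if not self.labels.isin(["low", "high"]).all():
            raise ValidationError("labels must be 'low' or 'high'")
        if self.cutoff_rule == "fraction" and not (self.q and 0 < self.q < 1):
            raise ValidationError("fraction rule requires q in (0,1)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit on a continuous score."""

    log_hr: float
    hr: float
    z: float
    p: float
    n: int
    n_events: int
    converged: bool = True


@dataclass(frozen=True)
class MetaResult:
    """Sample-size-weighted Stouffer combination of per-dataset z-scores."""

    per_dataset: list[tuple[float, float]]  # (z_i, n_i)
    meta_z: float
    meta_p: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.meta_z))


def _as_series(scores) -> pd.Series:
    s = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    if s.index.duplicated().any():
        raise ValidationError("duplicate sample ids in scores")
    return s.astype(float)


def split_by_fraction(scores, q: float) -> GroupSplit:
    """Label the round(q*n) highest-scoring samples 'high' (half-up rounding).

    Score ties straddling the boundary are resolved by sample id ascending,
    so the split is deterministic. Mirrors mutation-based group sizes when
    q is the cohort's TP53 mutation rate.
    """
    if not 0 < q < 1:
        raise ValidationError(f"q must be in (0,1), got {q}")
    s = _as_series(scores)
    if len(s) < 2:
        raise ValidationError("need >=2 samples to split")
    n_high = int(np.floor(q * len(s) + 0.5))  # round half up
    order = sorted(s.index, key=lambda sid: (-s[sid], sid))
    high = set(order[:n_high])
    labels = pd.Series(
        ["high" if sid in high else "low" for sid in s.index], index=s.index
    )
    return GroupSplit(labels, "fraction", q)


def split_by_median(scores) -> GroupSplit:
    """Label samples with score strictly above the median 'high'.

    Median-valued samples go to 'low', so one threshold demarcates the
    groups. Raises when all scores are identical (no split exists).
    """
    s = _as_series(scores)
    if len(s) < 2:
        raise ValidationError("need >=2 samples to split")
    if s.nunique() == 1:
        raise ValidationError("all scores identical; median split is degenerate")
    med = s.median()
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
    return GroupSplit(labels, "median")


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    n_low: int
    n_high: int
    events_low: int
    events_high: int


def logrank_test(split: GroupSplit, surv: SurvivalTable) -> LogrankResult:
    """Two-group log-rank test between the low and high groups.

    Samples are aligned between split and survival table first; p comes
    from a chi-square with 1 df.
    """
    labels, table = align_samples(split.labels, surv.table)
    low = labels == "low"
    high = labels == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ValidationError("both groups must be non-empty after alignment")
    if table["event"].sum() == 0:
        raise ValidationError("no events observed; log-rank is undefined")
    res = _ll_logrank(
        table.loc[low, "time"],
        table.loc[high, "time"],
        event_observed_A=table.loc[low, "event"],
        event_observed_B=table.loc[high, "event"],
    )
    return LogrankResult(
        chi_square=float(res.test_statistic),
        p=float(res.p_value),
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        events_low=int(table.loc[low, "event"].sum()),
        events_high=int(table.loc[high, "event"].sum()),
    )


def cox_univariate(scores, surv: SurvivalTable) -> CoxResult:
    """Univariate Cox proportional-hazards fit on a continuous score.

    Partial-likelihood MLE with Efron handling of tied event times
    (lifelines' default, matching R's coxph). Wald z and two-sided p.
    """
    s, table = align_samples(_as_series(scores), surv.table)
    if s.std(ddof=0) == 0:
        raise ValidationError("score has zero variance; Cox model unidentifiable")
    if table["event"].sum() == 0:
        raise ValidationError("no events observed; Cox model undefined")
    df = pd.DataFrame({"score": s, "time": table["time"], "event": table["event"]})
    cph = CoxPHFitter()
    converged = True
    # tighten Newton stopping so the MLE is resolved well past 1e-6
    fit_options = {"precision": 1e-12, "max_steps": 500}
    try:
        cph.fit(df, duration_col="time", event_col="event", fit_options=fit_options)
    except Exception as exc:
        logger.warning("Cox fit did not converge cleanly: %s", exc)
        cph = CoxPHFitter(penalizer=1e-6)
        try:
            cph.fit(df, duration_col="time", event_col="event")
            converged = False
        except Exception as exc2:
            raise ValidationError(f"Cox fit failed: {exc2}") from exc2
    log_hr = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    z = log_hr / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        log_hr=log_hr,
        hr=float(np.exp(log_hr)),
        z=float(z),
        p=float(min(max(p, np.finfo(float).tiny), 1.0)),
        n=len(df),
        n_events=int(df["event"].sum()),
        converged=converged,
    )


def meta_stouffer(results: list[tuple[float, float]]) -> MetaResult:
    """Combine per-dataset (z_i, n_i) pairs with sample-size weights.

    ``meta_z = sum(n_i z_i) / sqrt(sum(n_i^2))``; the two-sided p refers
    meta_z to the standard normal. Weights are scale-invariant: rescaling
    every n_i leaves meta_z unchanged.
    """
    if not results:
        raise ValidationError("meta-analysis needs at least one dataset")
    z = np.array([r[0] for r in results], dtype=float)
    n = np.array([r[1] for r in results], dtype=float)
    if (n <= 0).any():
        raise ValidationError("dataset sample sizes must be positive")
    meta_z = float(np.sum(n * z) / np.sqrt(np.sum(n**2)))
    meta_p = float(2.0 * stats.norm.sf(abs(meta_z)))
    return MetaResult(per_dataset=[(float(a), float(b)) for a, b in results],
                      meta_z=meta_z, meta_p=min(meta_p, 1.0))


def km_curve(split: GroupSplit, surv: SurvivalTable) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit estimate per group.

    Returns per group a DataFrame with columns ``time`` and ``survival``
    (monotone non-increasing from 1.0 at time 0).
    """
    labels, table = align_samples(split.labels, surv.table)
    out: dict[str, pd.DataFrame] = {}
    for name in ("low", "high"):
        mask = labels == name
        if mask.sum() == 0:
            raise ValidationError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[mask, "time"], table.loc[mask, "event"])
        sf = kmf.survival_function_
        out[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out
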