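"""Synthetic cohorts with the statistical structure the analysis assumes.

Expression is Gaussian background noise with a subset of "truth" genes
shifted in mutant samples: up-genes by +effect SD, down-genes by -effect
SD. Every downstream step is rank- or regression-based, so only the
ordering geometry of the shift matters, not a count-like marginal
distribution. A sample's true deficiency is the standardized contrast
mean(up truth genes) - mean(down truth genes); survival times are
exponential with hazard ``baseline_hazard * exp(surv_log_hr * deficiency)``
and independent exponential censoring whose rate is solved to hit the
requested censoring fraction in expectation; drug response decreases
linearly in deficiency with Gaussian noise, floored at zero.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_core import (
    DrugResponse,
    ExpressionMatrix,
    MutationStatus,
    SurvivalTable,
    ValidationError,
    write_drug_response,
    write_expression,
    write_mutation_status,
    write_survival,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of one synthetic cohort.

    effect is the mutant mean shift in SD units on truth genes;
    surv_log_hr is the log hazard ratio per SD of true deficiency;
    baseline_hazard is in events per time unit (months by convention);
    censor_rate is the expected fraction of censored samples.
    """

    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    effect: float = 1.0
    mutation_rate: float = 0.47
    n_samples: int = 200
    noise_sd: float = 1.0
    surv_log_hr: float = 0.5
    baseline_hazard: float = 0.01
    censor_rate: float = 0.3
    drug_effect: float = 0.5
    drug_baseline: float = 3.0
    drug_noise_sd: float = 0.5
    seed: int = 17
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError("n_up + n_down must not exceed n_genes")
        if not 0.0 < self.mutation_rate < 1.0:
            raise ValidationError("mutation_rate must be in (0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must be in [0,1)")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValidationError("need >=2 samples and >=2 genes")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("noise_sd and baseline_hazard must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionMatrix
    mutations: MutationStatus
    survival: SurvivalTable
    drug: DrugResponse
    truth_up_genes: list[str]
    truth_down_genes: list[str]
    true_deficiency: pd.Series  # standardized, per sample
    config: SimulationConfig


def _censoring_rate_constant(hazards: np.ndarray, target: float) -> float:
    """Censoring rate c with E[fraction censored] = target, given subject
    hazards: with independent exponential censoring, P(censored_i) =
    c / (c + h_i); solve mean_i over c by bisection."""
    if target <= 0.0:
        return 0.0

    def f(c: float) -> float:
        return float(np.mean(c / (c + hazards)) - target)

    lo, hi = 1e-12, float(hazards.max())
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            break
    return float(brentq(f, lo, hi))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort (expression, mutation labels, survival, drug
    response) plus the generating truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    digits = max(3, len(str(n)))
    samples = [f"{config.sample_prefix}{i:0{digits}d}" for i in range(n)]
    genes = [f"g{i:05d}" for i in range(g)]
    up_genes = genes[: config.n_up]
    down_genes = genes[config.n_up : config.n_up + config.n_down]

    status = (rng.random(n) < config.mutation_rate).astype(int)
    # guarantee both classes so downstream fits are identifiable
    if status.sum() == 0:
        status[rng.integers(n)] = 1
    elif status.sum() == n:
        status[rng.integers(n)] = 0

    values = rng.normal(0.0, config.noise_sd, size=(g, n))
    mut = status == 1
    values[: config.n_up, mut] += config.effect * config.noise_sd
    values[config.n_up : config.n_up + config.n_down, mut] -= (
        config.effect * config.noise_sd
    )

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    up_mean = values[: config.n_up].mean(axis=0) if config.n_up else np.zeros(n)
    down_mean = (
        values[config.n_up : config.n_up + config.n_down].mean(axis=0)
        if config.n_down
        else np.zeros(n)
    )
    raw = up_mean - down_mean
    sd = raw.std(ddof=0)
    deficiency = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    deficiency = pd.Series(deficiency, index=samples, name="true_deficiency")

    hazards = config.baseline_hazard * np.exp(config.surv_log_hr * deficiency.to_numpy())
    event_times = rng.exponential(1.0 / hazards)
    c = _censoring_rate_constant(hazards, config.censor_rate)
    if c > 0:
        censor_times = rng.exponential(1.0 / c, size=n)
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        event = np.ones(n, dtype=int)
    surv = SurvivalTable(
        pd.DataFrame({"time": observed, "event": event}, index=samples)
    )

    area = (
        config.drug_baseline
        - config.drug_effect * deficiency.to_numpy()
        + rng.normal(0.0, config.drug_noise_sd, size=n)
    )
    drug = DrugResponse(pd.Series(np.maximum(area, 0.0), index=samples, name="activity_area"))

    return SyntheticCohort(
        expression=expr,
        mutations=MutationStatus(pd.Series(status, index=samples, name="status")),
        survival=surv,
        drug=drug,
        truth_up_genes=up_genes,
        truth_down_genes=down_genes,
        true_deficiency=deficiency,
        config=config,
    )


def simulate_meta_collection(
    configs: list[SimulationConfig],
) -> list[SyntheticCohort]:
    """Independent cohorts for meta-analysis, one per config.

    Each cohort gets a distinct sample-id namespace; duplicate seeds only
    warn (the cohorts would be identical draws)."""
    if len(configs) < 2:
        raise ValidationError("meta collection needs >=2 configs")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        import logging

        logging.getLogger(__name__).warning("duplicate seeds across meta configs")
    out = []
    for i, cfg in enumerate(configs):
        cfg = replace(cfg, sample_prefix=f"D{i}_{cfg.sample_prefix}")
        out.append(simulate_cohort(cfg))
    return out


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort's tables as TSV into out_dir; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "mutations": out_dir / "mutations.tsv",
        "survival": out_dir / "survival.tsv",
        "drug": out_dir / "drug.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_mutation_status(cohort.mutations, paths["mutations"])
    write_survival(cohort.survival, paths["survival"])
    write_drug_response(cohort.drug, paths["drug"])
    truth = pd.DataFrame(
        [(gid, "up") for gid in cohort.truth_up_genes]
        + [(gid, "down") for gid in cohort.truth_down_genes],
        columns=["gene", "direction"],
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_meta_manifest(
    cohorts: list[SyntheticCohort], out_dir: str | Path
) -> Path:
    """Write each cohort under out_dir/dataset_<i>/ plus a manifest TSV
    (dataset_id, scores_path placeholder, clinical_path, n) for the meta CLI."""
    out_dir = Path(out_dir)
    rows = []
    for i, cohort in enumerate(cohorts):
        d = out_dir / f"dataset_{i}"
        paths = write_cohort(cohort, d)
        rows.append(
            {
                "dataset_id": f"dataset_{i}",
                "expression_path": str(paths["expression"]),
                "mutations_path": str(paths["mutations"]),
                "clinical_path": str(paths["survival"]),
                "n": cohort.config.n_samples,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
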