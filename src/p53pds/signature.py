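"""Build cancer-type-specific p53 deficiency signatures.

For each gene, a univariate logistic regression is fitted with the gene's
(per-gene standardized) expression as the covariate and binary TP53
protein-altering mutation status as the outcome. The association p-value is
a likelihood-ratio test of the one-covariate model against the
intercept-only model; a likelihood-ratio p remains informative under
complete separation, where a Wald p would collapse to 1 for exactly the
strongest genes (Hauck-Donner effect).

Gene weights are ``w_g = min(-log10 p_g, 10) / 10``: the p-value is -log10
transformed, trimmed at 10 to damp outliers, and divided by the trim cap so
weights land in [0, 1] on a scale comparable across cancer types. Genes
with positive slope form the *up* profile, negative slope the *down*
profile; uncorrelated genes stay in their profile with a small weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import (
    DeficiencySignature,
    ExpressionMatrix,
    MutationStatus,
    ValidationError,
    align_samples,
)

logger = logging.getLogger(__name__)

WEIGHT_TRIM_CAP = 10.0  # -log10(p) values are trimmed here before scaling


@dataclass(frozen=True)
class GeneAssociation:
    """Per-gene logistic association with mutation status.

    ``beta`` is the slope per 1 SD of expression; ``p_value`` is the
    likelihood-ratio p. ``degenerate`` marks genes with no usable variation
    (constant expression), which carry beta = 0 and p = 1.
    """

    gene_id: str
    beta: float
    p_value: float
    n_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.gene_id}: p-value outside (0,1]: {self.p_value}")
        if not self.degenerate and not np.isfinite(self.beta):
            raise ValidationError(f"{self.gene_id}: non-finite beta without degenerate flag")


def _fit_one_gene(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Logistic fit of y on standardized x; returns (beta, LRT p-value)."""
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / convergence chatter
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, method="newton")
        except Exception:  # separation can make the Hessian singular
            res = model.fit(disp=0, maxiter=200, method="lbfgs")
    # LRT of slope model vs intercept-only; llnull is closed-form for Logit
    lr = 2.0 * (res.llf - res.llnull)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return float(res.params[1]), min(max(p, np.finfo(float).tiny), 1.0)


def fit_gene_associations(
    expr: ExpressionMatrix,
    status: MutationStatus,
    log2_transform: bool = False,
) -> list[GeneAssociation]:
    """Fit one logistic association per gene.

    Expression and status are aligned on their common samples first. Each
    gene's expression is standardized to mean 0, SD 1 before the fit so
    slopes are comparable across genes. ``log2_transform`` applies
    log2(x + 1) before standardization, for RSEM-like non-negative inputs.

    Raises if the aligned cohort is all-mutant or all-wild-type (the model
    is unidentifiable). Constant-expression genes are flagged degenerate
    with beta 0 and p 1.
    """
    expr, status = align_samples(expr, status)
    y = status.status.to_numpy(dtype=float)
    n = len(y)
    n_mut = int(y.sum())
    if n_mut == 0 or n_mut == n:
        raise ValidationError(
            f"cohort has {n_mut} mutants of {n} samples; need both classes to fit"
        )

    values = expr.values.to_numpy(dtype=float)
    if log2_transform:
        if (values < 0).any():
            raise ValidationError("log2 transform requires non-negative expression")
        values = np.log2(values + 1.0)

    out: list[GeneAssociation] = []
    for gi, gene in enumerate(expr.gene_ids):
        x = values[gi]
        sd = x.std(ddof=0)
        if sd == 0.0:
            out.append(GeneAssociation(gene, 0.0, 1.0, n, degenerate=True))
            continue
        z = (x - x.mean()) / sd
        try:
            beta, p = _fit_one_gene(z, y)
        except Exception:  # singular / pathological fit: no evidence claimed
            out.append(GeneAssociation(gene, 0.0, 1.0, n, degenerate=True))
            continue
        if not np.isfinite(beta):
            out.append(GeneAssociation(gene, 0.0, 1.0, n, degenerate=True))
            continue
        out.append(GeneAssociation(gene, beta, p, n))
    return out


def weight_from_p(p_value: float) -> float:
    """w = min(-log10 p, cap) / cap, mapping p-values onto [0, 1]."""
    return min(-np.log10(p_value), WEIGHT_TRIM_CAP) / WEIGHT_TRIM_CAP


def build_signature(
    assocs: list[GeneAssociation], cancer_type_label: str = ""
) -> DeficiencySignature:
    """Turn per-gene associations into an up/down weighted signature.

    Genes with beta > 0 go to the up profile, beta < 0 to the down profile,
    each with weight ``weight_from_p(p)``. Degenerate genes (beta exactly 0)
    carry no information and join neither profile. All non-degenerate genes
    are retained, including near-zero weights.
    """
    if not assocs:
        raise ValidationError("empty association list")
    up: dict[str, float] = {}
    down: dict[str, float] = {}
    for a in assocs:
        if a.degenerate or a.beta == 0.0:
            continue
        w = weight_from_p(a.p_value)
        (up if a.beta > 0 else down)[a.gene_id] = w
    sig = DeficiencySignature(up, down, cancer_type_label)
    if not sig.is_usable():
        logger.warning(
            "signature %r has no strictly positive weight in one or both profiles; "
            "it will not produce meaningful scores",
            cancer_type_label,
        )
    return sig


def signature_correlation(
    sig_a: DeficiencySignature, sig_b: DeficiencySignature
) -> float:
    """Spearman correlation between two signatures.

    Each signature is flattened to one signed weight vector over the union
    of both signatures' genes: up weights positive, down weights negative,
    absent genes 0. Requires at least 3 common genes between the two
    flattened vectors' support union.
    """
    universe = sorted(sig_a.genes | sig_b.genes)
    common = sig_a.genes & sig_b.genes
    if len(common) < 3:
        raise ValidationError(f"need >=3 genes in common, got {len(common)}")

    def flat(sig: DeficiencySignature) -> np.ndarray:
        v = np.zeros(len(universe))
        for i, g in enumerate(universe):
            if g in sig.up_weights:
                v[i] = sig.up_weights[g]
            elif g in sig.down_weights:
                v[i] = -sig.down_weights[g]
        return v

    rho, _ = stats.spearmanr(flat(sig_a), flat(sig_b))
    return float(rho)


def associations_frame(assocs: list[GeneAssociation]) -> pd.DataFrame:
    """Associations as a DataFrame (gene, beta, p_value, n_used, degenerate)."""
    return pd.DataFrame(
        [(a.gene_id, a.beta, a.p_value, a.n_used, a.degenerate) for a in assocs],
        columns=["gene", "beta", "p_value", "n_used", "degenerate"],
    ).set_index("gene")
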