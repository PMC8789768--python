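"""Sample-specific deficiency scores by rank-based weighted enrichment.

For one sample, genes are sorted by expression, descending (ties broken by
gene id, ascending, so rankings are reproducible across platforms). Given
weights ``w`` in [0, 1] listed in that rank order, the enrichment score
compares the cumulative foreground distribution

    F(i) = sum_{j<=i} w_j / sum_j w_j

against the cumulative background

    B(i) = sum_{j<=i} (1 - w_j) / sum_j (1 - w_j)

and returns ``ES = F(i*) - B(i*)`` at the prefix ``i*`` maximizing
``|F - B|`` (ties resolved to the smallest prefix). A positive ES means the
high-weight genes concentrate among the sample's most highly expressed
genes. ES is normalized against random re-assignments of the weights over
rank positions (``NES = ES / mean |ES_perm|``), and a sample's p53
deficiency score is ``pds = nes_up - nes_down``: higher score, lower
inferred p53 activity.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .io_core import (
    DeficiencySignature,
    ExpressionMatrix,
    PdsResult,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_SEED = 17
_DEGENERATE_DENOM = 1e-12


def _check_weights(w: np.ndarray) -> None:
    if w.size < 2:
        raise ValidationError("need at least 2 genes")
    if np.any((w < 0) | (w > 1)):
        raise ValidationError("weights must lie in [0, 1]")
    if not np.any(w > 0):
        raise ValidationError("all weights zero: empty profile")
    if not np.any(w < 1):
        raise ValidationError("all weights one: no background genes")


def enrichment_score(ranked_weights: Sequence[float]) -> float:
    """Signed ES in [-1, 1] for weights listed in descending-expression order."""
    w = np.asarray(ranked_weights, dtype=float)
    _check_weights(w)
    f = np.cumsum(w) / w.sum()
    b = np.cumsum(1.0 - w) / (1.0 - w).sum()
    gap = f - b
    i_star = int(np.argmax(np.abs(gap)))  # argmax takes the first maximum
    return float(gap[i_star])


def _es_batch(weight_rows: np.ndarray) -> np.ndarray:
    """Row-wise ES for a (k, n_genes) matrix of weight orderings."""
    f = np.cumsum(weight_rows, axis=1) / weight_rows.sum(axis=1, keepdims=True)
    b = np.cumsum(1.0 - weight_rows, axis=1) / (1.0 - weight_rows).sum(axis=1, keepdims=True)
    gap = f - b
    idx = np.argmax(np.abs(gap), axis=1)
    return gap[np.arange(gap.shape[0]), idx]


def permutation_null_mean(
    weights: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Mean |ES| over random permutations of the weight vector across ranks.

    This null depends only on the multiset of weights and the number of
    genes, not on any particular sample's ordering, so it can be shared by
    every sample scored against the same profile and gene universe.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    w = np.asarray(weights, dtype=float)
    _check_weights(w)
    perms = np.empty((n_perm, w.size))
    for k in range(n_perm):
        perms[k] = w[rng.permutation(w.size)]
    return float(np.mean(np.abs(_es_batch(perms))))


def normalized_score(
    ranked_weights: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
) -> float:
    """NES = ES / mean(|ES| over permuted weight orderings), seeded.

    If the permutation null is degenerate (every ordering yields |ES| below
    1e-12, e.g. all-equal weights), NES is defined as 0.
    """
    w = np.asarray(ranked_weights, dtype=float)
    es = enrichment_score(w)
    rng = np.random.default_rng(seed)
    denom = permutation_null_mean(w, n_perm, rng)
    if denom < _DEGENERATE_DENOM:
        return 0.0
    return float(es / denom)


def rank_sample(expr: ExpressionMatrix, sample_id: str) -> list[str]:
    """Gene ids sorted by the sample's expression, descending; ties broken
    by gene id ascending."""
    col = expr.values[sample_id]
    order = sorted(expr.gene_ids, key=lambda g: (-col[g], g))
    return order


def _ranked_weight_matrix(
    expr: ExpressionMatrix, weight_by_gene: dict[str, float]
) -> np.ndarray:
    """(n_samples, n_genes) matrix: row s holds profile weights in sample
    s's descending-expression gene order. Genes absent from the profile get
    weight 0 (background only)."""
    genes = np.array(expr.gene_ids)
    w = np.array([weight_by_gene.get(g, 0.0) for g in genes])
    vals = expr.values.to_numpy(dtype=float)
    # stable sort on gene id ascending, then stable descending sort on value
    id_order = np.argsort(genes, kind="stable")
    out = np.empty((expr.n_samples, len(genes)))
    for s in range(expr.n_samples):
        col = vals[id_order, s]
        expr_order = id_order[np.argsort(-col, kind="stable")]
        out[s] = w[expr_order]
    return out


def compute_pds(
    expr: ExpressionMatrix,
    sig: DeficiencySignature,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
) -> list[PdsResult]:
    """Score every sample of the matrix against a deficiency signature.

    Each profile is restricted to genes present in the matrix; matrix genes
    outside the profile contribute to the background with weight 0. The
    permutation-null denominator is computed once per profile and shared
    across samples (it does not depend on the sample ordering). Raises when
    no signature gene overlaps the matrix; warns when fewer than half do.
    """
    matrix_genes = set(expr.gene_ids)
    present = sig.genes & matrix_genes
    if len(present) < 2:
        raise ValidationError(
            f"only {len(present)} signature gene(s) present in the matrix; need >=2"
        )
    frac = len(present) / len(sig.genes)
    if frac < 0.5:
        logger.warning(
            "only %d/%d (%.0f%%) signature genes found in the matrix",
            len(present),
            len(sig.genes),
            100 * frac,
        )
    missing = len(sig.genes) - len(present)
    if missing:
        logger.info("dropped %d signature genes absent from the matrix", missing)

    results: dict[str, dict[str, float]] = {
        s: {} for s in expr.sample_ids
    }
    for name, profile in (("up", sig.up_weights), ("down", sig.down_weights)):
        ranked = _ranked_weight_matrix(expr, profile)
        es = _es_batch(ranked)
        # fresh identically-seeded RNG per profile, matching normalized_score;
        # identical profiles then get identical nulls and cancel exactly
        rng = np.random.default_rng(seed)
        denom = permutation_null_mean(ranked[0], n_perm, rng)
        nes = np.zeros_like(es) if denom < _DEGENERATE_DENOM else es / denom
        for i, s in enumerate(expr.sample_ids):
            results[s][f"es_{name}"] = float(es[i])
            results[s][f"nes_{name}"] = float(nes[i])

    return [
        PdsResult(
            sample_id=s,
            es_up=r["es_up"],
            es_down=r["es_down"],
            nes_up=r["nes_up"],
            nes_down=r["nes_down"],
            pds=r["nes_up"] - r["nes_down"],
        )
        for s, r in results.items()
    ]


def pds_series(results: Sequence[PdsResult]):
    """Per-sample pds values as a pandas Series (sample id index)."""
    import pandas as pd

    return pd.Series({r.sample_id: r.pds for r in results}, name="pds")
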