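import numpy as np
import pandas as pd
import pytest

import p53pds as P


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-effect toy cohort: 300 genes, 20+20 truth, 80 samples."""
    return P.simulate_cohort(
        P.SimulationConfig(n_genes=300, n_up=20, n_down=20, n_samples=80, seed=3)
    )


@pytest.fixture(scope="session")
def small_signature(small_cohort):
    assocs = P.fit_gene_associations(small_cohort.expression, small_cohort.mutations)
    return P.build_signature(assocs, "toy")


@pytest.fixture(scope="session")
def small_scores(small_cohort, small_signature):
    res = P.compute_pds(small_cohort.expression, small_signature, n_perm=200, seed=7)
    return P.pds_series(res)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Study-condition cohort: effect 1 SD, 50+50 truth genes of 2000, n=200."""
    return P.simulate_cohort(
        P.SimulationConfig(n_genes=2000, n_up=50, n_down=50, effect=1.0,
                           n_samples=200, seed=1)
    )


@pytest.fixture(scope="session")
def recovery_signature(recovery_cohort):
    assocs = P.fit_gene_associations(recovery_cohort.expression,
                                     recovery_cohort.mutations)
    return P.build_signature(assocs)


@pytest.fixture(scope="session")
def recovery_scores(recovery_cohort, recovery_signature):
    res = P.compute_pds(recovery_cohort.expression, recovery_signature,
                        n_perm=1000, seed=17)
    return P.pds_series(res)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_es(weights):
    """Independent ES oracle: evaluate F and B at every prefix directly
    from their definitions, no cumulative shortcuts."""
    w = list(map(float, weights))
    n = len(w)
    sw = sum(w)
    sb = sum(1.0 - x for x in w)
    best_gap, best_val = -1.0, 0.0
    for i in range(1, n + 1):
        f = sum(w[:i]) / sw
        b = sum(1.0 - x for x in w[:i]) / sb
        if abs(f - b) > best_gap:
            best_gap = abs(f - b)
            best_val = f - b
    return best_val
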