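"""Group splits, log-rank, Cox partial likelihood, Stouffer meta."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

import p53pds as P
from p53pds.io_core import SurvivalTable, ValidationError
from p53pds.survival_stats import (
    GroupSplit,
    cox_univariate,
    km_curve,
    logrank_test,
    meta_stouffer,
    split_by_fraction,
    split_by_median,
)


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=ids))


def _split(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return GroupSplit(pd.Series(labels, index=ids), "median")


class TestSplits:
    def test_fraction_half_of_ten(self):
        s = pd.Series(range(10), index=[f"s{i}" for i in range(10)], dtype=float)
        assert split_by_fraction(s, 0.5).n_high == 5

    def test_fraction_top_three(self):
        s = pd.Series([5, 1, 9, 3, 7, 2, 8, 4, 6, 0],
                      index=[f"s{i}" for i in range(10)], dtype=float)
        split = split_by_fraction(s, 0.3)
        high = set(split.labels[split.labels == "high"].index)
        assert high == {"s2", "s6", "s4"}  # scores 9, 8, 7

    def test_fraction_tie_broken_by_sample_id(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=["d", "c", "b", "a"])
        split1 = split_by_fraction(s, 0.5)
        split2 = split_by_fraction(s.sort_index(), 0.5)
        # explicit sort oracle: by (-score, id) -> a(3), b(2), c(2), d(1)
        assert set(split1.labels[split1.labels == "high"].index) == {"a", "b"}
        pd.testing.assert_series_equal(split1.labels.sort_index(),
                                       split2.labels.sort_index())

    def test_invalid_fraction_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            split_by_fraction(s, 1.5)

    def test_median_simple(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        split = split_by_median(s)
        assert set(split.labels[split.labels == "high"].index) == {"c", "d"}

    def test_median_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        split = split_by_median(s)  # median 2; only strict > is high
        assert set(split.labels[split.labels == "high"].index) == {"d"}

    def test_median_partition_property(self, rng):
        s = pd.Series(rng.normal(size=101), index=[f"s{i}" for i in range(101)])
        split = split_by_median(s)
        low = s[split.labels == "low"]
        high = s[split.labels == "high"]
        assert len(low) + len(high) == 101
        assert low.max() <= s.median() < high.min()

    def test_median_degenerate_rejected(self):
        s = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        with pytest.raises(ValidationError):
            split_by_median(s)


class TestLogrank:
    def test_identical_groups_null(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        split = _split(["low"] * 3 + ["high"] * 3)
        res = logrank_test(split, surv)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_life_table(self):
        # group low: events at 1, 2; group high: events at 3, 4.
        # O-E tables give O_low - E_low = 7/6, V = 17/36, chi2 = 49/17.
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        split = _split(["low", "low", "high", "high"])
        res = logrank_test(split, surv)
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-9)
        assert res.p == pytest.approx(stats.chi2.sf(49 / 17, 1), abs=1e-9)

    def test_relabel_invariance(self, rng):
        surv = _surv(rng.exponential(10, 40), rng.integers(0, 2, 40))
        labels = ["low"] * 20 + ["high"] * 20
        a = logrank_test(_split(labels), surv)
        b = logrank_test(_split([{"low": "high", "high": "low"}[l] for l in labels]), surv)
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p == pytest.approx(b.p)

    def test_strong_separation_detected(self):
        c = P.simulate_cohort(
            P.SimulationConfig(n_genes=2, n_up=1, n_down=1, effect=0.0,
                               n_samples=200, surv_log_hr=np.log(3.0), seed=8)
        )
        split = split_by_median(c.true_deficiency)
        assert logrank_test(split, c.survival).p < 0.01

    def test_single_group_rejected(self):
        surv = _surv([1, 2], [1, 1])
        with pytest.raises(ValidationError):
            logrank_test(_split(["low", "low"]), surv)


def partial_likelihood_neg(beta, times, events, x):
    """Written-out Cox partial likelihood (no ties) for the grid oracle."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return -ll


class TestCox:
    def test_five_subject_toy_matches_grid_oracle(self):
        times = [2.0, 4.0, 6.0, 8.0, 10.0]
        events = [1, 1, 0, 1, 1]
        x = [0.5, -1.0, 0.8, -0.3, 0.9]
        surv = _surv(times, events)
        scores = pd.Series(x, index=surv.sample_ids)
        res = cox_univariate(scores, surv)
        opt = minimize_scalar(partial_likelihood_neg, bounds=(-5, 5),
                              args=(times, events, x), method="bounded",
                              options={"xatol": 1e-10})
        assert res.log_hr == pytest.approx(opt.x, abs=1e-6)

    def test_sign_contract(self):
        # higher score always precedes events
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        surv = _surv(times, [1] * 6)
        scores = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], index=surv.sample_ids)
        assert cox_univariate(scores, surv).log_hr > 0

    def test_null_scores_not_significant(self, rng):
        zs = []
        for rep in range(20):
            n = 500
            times = rng.exponential(10.0, n)
            events = (rng.random(n) < 0.7).astype(int)
            surv = _surv(times, events)
            scores = pd.Series(rng.normal(size=n), index=surv.sample_ids)
            zs.append(cox_univariate(scores, surv).z)
        assert max(abs(z) for z in zs) < 3.5
        # z roughly standard normal under the null
        assert abs(np.mean(zs)) < 0.7

    def test_zero_variance_rejected(self):
        surv = _surv([1.0, 2.0, 3.0], [1, 1, 1])
        scores = pd.Series([1.0, 1.0, 1.0], index=surv.sample_ids)
        with pytest.raises(ValidationError):
            cox_univariate(scores, surv)

    def test_recovery_under_true_hazard(self):
        c = P.simulate_cohort(
            P.SimulationConfig(n_genes=2, n_up=1, n_down=1, effect=0.0,
                               n_samples=300, surv_log_hr=0.5, seed=12)
        )
        res = cox_univariate(c.true_deficiency, c.survival)
        assert res.log_hr > 0 and res.p < 0.01


class TestMetaStouffer:
    def test_single_dataset_identity(self):
        assert meta_stouffer([(1.7, 55)]).meta_z == pytest.approx(1.7)

    def test_closed_form_two_equal_datasets(self):
        res = meta_stouffer([(2.0, 100), (2.0, 100)])
        assert res.meta_z == pytest.approx(2.0 * np.sqrt(2.0), abs=1e-12)

    def test_cancellation(self):
        res = meta_stouffer([(1.0, 50), (-1.0, 50)])
        assert res.meta_z == 0.0 and res.meta_p == pytest.approx(1.0)

    def test_weight_scale_invariance(self, rng):
        pairs = [(float(z), float(n)) for z, n in
                 zip(rng.normal(size=6), rng.integers(20, 500, 6))]
        scaled = [(z, 7.5 * n) for z, n in pairs]
        assert meta_stouffer(pairs).meta_z == pytest.approx(
            meta_stouffer(scaled).meta_z, abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            meta_stouffer([])


class TestKmCurve:
    def test_no_censoring_product_limit(self):
        surv = _surv([1, 2, 3, 9, 9], [1, 1, 1, 0, 0],
                     ids=list("abcde"))
        split = _split(["low"] * 3 + ["high"] * 2, ids=list("abcde"))
        km = km_curve(split, surv)["low"]
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat(self):
        surv = _surv([5, 6, 7, 8], [0, 0, 0, 0])
        split = _split(["low", "low", "high", "high"])
        km = km_curve(split, surv)
        assert (km["low"]["survival"] == 1.0).all()
        assert (km["high"]["survival"] == 1.0).all()

    def test_mixed_censoring_matches_hand_table(self):
        # low group: event at 1 (3 at risk), censored at 2, event at 3
        # S: 1 -> 2/3 -> 2/3 -> 2/3 * 0 = 0
        surv = _surv([1, 2, 3, 5, 6], [1, 0, 1, 1, 1], ids=list("abcde"))
        split = _split(["low"] * 3 + ["high"] * 2, ids=list("abcde"))
        km = km_curve(split, surv)["low"]
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert (np.diff(km["survival"]) <= 1e-12).all()
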