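"""Survival statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from bridgemil.survival_eval import (aggregate_cv, concordance_index,
                                     cox_univariate, km_and_logrank,
                                     median_stratify)


def brute_force_concordance(times, events, risks):
    """Independent pair enumerator: ordered pairs, the documented rules."""
    n = len(times)
    pairs = conc = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                pairs += 1
                if risks[i] > risks[j]:
                    conc += 1
                elif risks[i] == risks[j]:
                    conc += 0.5
    return conc / pairs, int(pairs), conc


class TestConcordance:
    @pytest.mark.parametrize("times,events,risks,expected", [
        ((1, 2, 3), (1, 1, 1), (3, 2, 1), 1.0),     # perfect ranking
        ((1, 2, 3), (1, 1, 1), (1, 2, 3), 0.0),     # reversed ranking
        ((2, 4, 4), (1, 1, 0), (5, 5, 1), 0.75),    # tie rules
    ])
    def test_known_values(self, times, events, risks, expected):
        res = concordance_index(times, events, risks)
        assert res.c_index == pytest.approx(expected)

    def test_tied_time_pairs_excluded(self):
        res = concordance_index((2, 4, 4), (1, 1, 0), (5, 5, 1))
        assert res.n_comparable_pairs == 2
        assert res.n_concordant == 1.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        n = 200
        times = np.round(rng.exponential(5, n), 1)  # induces time ties
        events = rng.integers(0, 2, n)
        risks = np.round(rng.normal(0, 1, n), 1)    # induces risk ties
        events[0] = 1
        res = concordance_index(times, events, risks)
        c, pairs, conc = brute_force_concordance(times, events, risks)
        assert res.c_index == c
        assert res.n_comparable_pairs == pairs
        assert res.n_concordant == conc

    def test_complement_symmetry_tie_free(self):
        rng = np.random.default_rng(0)
        times = rng.permutation(50) + 1.0
        events = rng.integers(0, 2, 50)
        events[times.argmin()] = 1
        risks = rng.normal(size=50)
        c1 = concordance_index(times, events, risks).c_index
        c2 = concordance_index(times, events, -risks).c_index
        assert c1 + c2 == pytest.approx(1.0)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index((1, 1), (1, 1), (1, 2))


class TestAggregateCV:
    def test_t_interval_closed_form(self):
        agg = aggregate_cv([0.6, 0.65, 0.7, 0.7, 0.85])
        assert agg["mean"] == pytest.approx(0.70)
        assert agg["ci_low"] == pytest.approx(0.5838, abs=1e-3)
        assert agg["ci_high"] == pytest.approx(0.8162, abs=1e-3)

    def test_identical_folds_zero_width(self):
        agg = aggregate_cv([0.7] * 5)
        assert agg["ci_low"] == pytest.approx(agg["ci_high"]) == 0.7

    def test_permutation_invariant(self):
        a = aggregate_cv([0.6, 0.7, 0.8])
        b = aggregate_cv([0.8, 0.6, 0.7])
        assert a == b

    def test_single_fold_flagged(self):
        agg = aggregate_cv([0.7])
        assert agg["ci_low"] is None and "undefined" in agg["method"]


class TestMedianStratify:
    def test_even_split(self):
        assert median_stratify([1, 2, 3, 4]).tolist() == \
            ["low", "low", "high", "high"]

    def test_odd_median_goes_low(self):
        assert median_stratify([1, 2, 3]).tolist() == ["low", "low", "high"]

    def test_shift_invariance(self):
        r = np.array([3.0, 1.0, 7.0, 2.0])
        assert (median_stratify(r) == median_stratify(r + 100)).all()

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_stratify([2, 2, 2])


class TestKMLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        g = ["a"] * 4 + ["b"] * 4
        res = km_and_logrank(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_product_limit_closed_form(self):
        # group a: events at 1 and 2 -> S = 1, 0.5, 0
        res = km_and_logrank([1, 2, 3, 4], [1, 1, 1, 1],
                             ["a", "a", "b", "b"])
        a = res.curves[res.curves["group"] == "a"]
        surv = dict(zip(a["time"], a["survival"]))
        assert surv[1.0] == pytest.approx(0.5)
        assert surv[2.0] == pytest.approx(0.0)

    def test_separated_groups_chi2(self):
        # hand-computed O-E table gives chi2 = 2.8824
        res = km_and_logrank([1, 2, 3, 4], [1, 1, 1, 1],
                             ["a", "a", "b", "b"])
        assert res.logrank_chi2 == pytest.approx(2.882352941, abs=1e-6)

    def test_label_swap_invariance(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 0, 1, 1, 0]
        g1 = ["a", "a", "a", "b", "b", "b"]
        g2 = ["b", "b", "b", "a", "a", "a"]
        assert km_and_logrank(t, e, g1).logrank_chi2 == \
            pytest.approx(km_and_logrank(t, e, g2).logrank_chi2)

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 30)
        res = km_and_logrank(np.concatenate([t, t + 100]),
                             np.ones(60, dtype=int),
                             ["a"] * 30 + ["b"] * 30)
        a = res.curves[res.curves["group"] == "a"].sort_values("time")
        ts = np.sort(t)
        for i, (_, row) in enumerate(a.iloc[1:].iterrows()):
            emp = (t > ts[i]).mean()
            assert row["survival"] == pytest.approx(emp)


def breslow_partial_loglik(b, times, events, x):
    """Independent oracle: direct enumeration of the partial likelihood."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += b * x[i] - np.log(np.sum(np.exp(b * np.asarray(x)[risk])))
    return ll


class TestCox:
    def test_matches_independent_maximizer(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_univariate(t, e, x)
        opt = minimize_scalar(lambda b: -breslow_partial_loglik(b, t, e, x),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-6)
        assert not res.diverged

    def test_matches_maximizer_with_censoring_and_ties(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(5, 40), 0) + 1
        e = rng.integers(0, 2, 40)
        e[0] = 1
        x = rng.normal(size=40)
        res = cox_univariate(t, e, x)
        opt = minimize_scalar(lambda b: -breslow_partial_loglik(b, t, e, x),
                              bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-6)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(12)
        n = 2000
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        x = rng.normal(size=n)   # independent of outcome
        res = cox_univariate(t, e, x)
        assert abs(res.beta) < 0.1

    def test_separation_flagged(self):
        res = cox_univariate([1.0, 2.0], [1, 1], [0.0, 1.0])
        assert res.diverged

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3], [1, 1, 1], [1, 1, 1])
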