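"""Cohort statistics against enumeration and hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as ss
from scipy.special import comb

from iotnl import (
    correlation,
    cox_hr,
    evaluate_dichotomy,
    fisher_exact_two_sided,
    km_logrank,
    mann_whitney_u,
    optimize_editing_cutoff,
    roc_auc,
    youden_cutoff,
)
from iotnl.simulate import simulate_planted_cutoff_cohort


def pairs_auc(scores, labels):
    """All-pairs oracle: P(pos > neg) + 1/2 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_all_pairs_oracle_on_toy_table(self):
        scores = [0.1, 0.4, 0.4, 0.7, 0.2, 0.9, 0.5, 0.4]
        labels = [0, 0, 1, 1, 0, 1, 0, 1]
        assert roc_auc(scores, labels) == pytest.approx(pairs_auc(scores, labels))

    @given(seed=st.integers(0, 500))
    def test_matches_all_pairs_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.all() or not labels.any():
            return
        assert roc_auc(scores, labels) == pytest.approx(pairs_auc(scores, labels))

    @given(seed=st.integers(0, 200))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 10, size=30)
        labels = np.r_[np.ones(10), np.zeros(20)].astype(bool)
        base = roc_auc(scores, labels)
        assert roc_auc(np.log10(scores + 0.01), labels) == pytest.approx(base)
        assert roc_auc(np.exp(scores / 3), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc([1, 2], [1, 1])


class TestYoudenCutoff:
    def test_separable_scores(self):
        cut, sens, spec = youden_cutoff([1, 2, 9, 10], [0, 0, 1, 1])
        assert 2 < cut < 9
        assert sens == 1.0 and spec == 1.0

    def test_identical_scores_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            cut, sens, spec = youden_cutoff([3, 3, 3, 3], [0, 1, 0, 1])
        assert sens + spec - 1 == pytest.approx(0.0)

    @given(seed=st.integers(0, 300))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 8), size=20)
        labels = rng.integers(0, 2, size=20).astype(bool)
        if labels.all() or not labels.any():
            return
        cut, sens, spec = youden_cutoff(scores, labels)
        # oracle: scan every threshold between -inf and +inf
        uniq = np.unique(scores)
        cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
        best_j = max(
            ((scores > c) & labels).sum() / labels.sum()
            + ((scores <= c) & ~labels).sum() / (~labels).sum()
            - 1.0
            for c in cands
        )
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_dichotomizing_at_cutoff_reproduces_sens_spec(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30).astype(bool)
        cut, sens, spec = youden_cutoff(scores, labels)
        hi = scores > cut
        assert sens == pytest.approx((hi & labels).sum() / labels.sum())
        assert spec == pytest.approx((~hi & ~labels).sum() / (~labels).sum())


def fisher_enumeration(table):
    """Exhaustive two-sided Fisher oracle: sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,printed,places",
        [
            ([[5, 7], [1, 17]], 0.0256, 4),
            ([[4, 1], [4, 8]], 0.131, 3),
            ([[7, 0], [3, 11]], 0.001, 3),
        ],
    )
    def test_reference_tables(self, table, printed, places):
        assert round(fisher_exact_two_sided(table), places) == pytest.approx(printed)

    @given(seed=st.integers(0, 500))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 31, size=(2, 2))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        assert fisher_exact_two_sided(t) == pytest.approx(fisher_enumeration(t), abs=1e-9)

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_two_sided([[0, 5], [0, 9]]) == 1.0


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/C(6,3) doubled tail

    def test_exact_matches_rank_enumeration(self):
        x, y = [1.5, 3.2, 7.1], [2.0, 4.4, 5.5, 9.9]
        _, p = mann_whitney_u(x, y)
        combined = sorted(x + y)
        n1 = len(x)
        u_obs = sum(1 for xi in x for yj in y if xi > yj)
        us = []
        for idx in itertools.combinations(range(len(combined)), n1):
            xs = [combined[i] for i in idx]
            ys = [combined[i] for i in range(len(combined)) if i not in idx]
            us.append(sum(1 for xi in xs for yj in ys if xi > yj))
        us = np.array(us)
        mu = len(x) * len(y) / 2
        tail = (us <= min(u_obs, 2 * mu - u_obs)).mean() + (us >= max(u_obs, 2 * mu - u_obs)).mean()
        assert p == pytest.approx(tail)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_power_against_monte_carlo_oracle(self):
        """Rejection rate under a 1-sd shift matches a direct MC estimate."""
        rng = np.random.default_rng(77)
        n_reps = 300
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            if mann_whitney_u(x, y)[1] < 0.05:
                rejections += 1
        rate = rejections / n_reps
        # asymptotic power of the rank test at this shift and n is ~0.999
        assert rate > 0.97

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestKmLogrank:
    def test_fully_separated_groups(self):
        res = km_logrank([([10] * 5, [1] * 5), ([100] * 5, [1] * 5)], ["a", "b"])
        assert res["medians"]["a"] == 10 and res["medians"]["b"] == 100
        assert res["logrank_p"] < 0.01

    def test_identical_groups(self):
        t = [5, 10, 15, 20, 25, 30]
        e = [1, 1, 0, 1, 1, 0]
        res = km_logrank([(t, e), (t, e)])
        assert res["logrank_p"] == pytest.approx(1.0, abs=0.01)

    def test_hand_computed_risk_table(self):
        """12 patients with censoring: O-E sums and chi-square from a by-hand table.

        Group A times (event): 2(1) 4(1) 6(0) 8(1) 10(1) 12(0)
        Group B times (event): 3(1) 5(0) 7(1) 9(1) 11(0) 13(1)
        """
        ta, ea = [2, 4, 6, 8, 10, 12], [1, 1, 0, 1, 1, 0]
        tb, eb = [3, 5, 7, 9, 11, 13], [1, 0, 1, 1, 0, 1]
        # by-hand Mantel-Haenszel: at each event time, expected events in A =
        # d_total * nA_at_risk / n_at_risk
        events = sorted({t for t, e in zip(ta + tb, ea + eb) if e})
        o_minus_e = 0.0
        var = 0.0
        for t in events:
            na = sum(1 for x in ta if x >= t)
            nb = sum(1 for x in tb if x >= t)
            n = na + nb
            da = sum(1 for x, e in zip(ta, ea) if x == t and e)
            db = sum(1 for x, e in zip(tb, eb) if x == t and e)
            d = da + db
            o_minus_e += da - d * na / n
            if n > 1:
                var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        chi2 = o_minus_e**2 / var
        expected_p = 1 - ss.chi2.cdf(chi2, 1)
        res = km_logrank([(ta, ea), (tb, eb)])
        assert res["chi2"] == pytest.approx(chi2, rel=1e-6)
        assert res["logrank_p"] == pytest.approx(expected_p, rel=1e-6)

    def test_median_not_reached_reported_as_none(self):
        # one early event among four patients leaves S(t) = 0.75 > 0.5
        res = km_logrank([([10, 20, 30, 40], [1, 0, 0, 0]), ([1, 2, 3], [1, 1, 1])])
        assert res["medians"]["0"] is None

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning, match="no events"):
            res = km_logrank([([5, 6], [0, 0]), ([7, 8], [0, 0])])
        assert res["logrank_p"] is None


class TestCoxHr:
    def test_identical_hazards_give_unit_hr(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(100, n)  # hazard independent of x
        res = cox_hr(x, t, np.ones(n, dtype=int))
        assert res["hr"] == pytest.approx(1.0, abs=0.25)
        assert res["ci95"][0] < res["hr"] < res["ci95"][1]

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(0)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        base = 0.01
        t = rng.exponential(1 / (base * np.exp(np.log(2.0) * x)))
        cens = rng.exponential(2 / base, size=n)
        times, events = np.minimum(t, cens), (t <= cens).astype(int)
        res = cox_hr(x, times, events)
        assert 1.7 <= res["hr"] <= 2.35

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_hr([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_hr([0, 1, 0], [1, 2, 3], [0, 0, 0])


class TestCorrelation:
    def test_linear_relation_pearson(self):
        x = np.arange(10.0)
        r, p = correlation(x, 2 * x, "pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_monotone_transform_spearman(self):
        x = np.linspace(1, 5, 12)
        r, _ = correlation(x, np.exp(x), "spearman")
        assert r == pytest.approx(1.0)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.uniform(size=10)
        y = rng.uniform(size=10)
        r_s, _ = correlation(x, y, "spearman")
        r_ranks, _ = correlation(ss.rankdata(x), ss.rankdata(y), "pearson")
        assert r_s == pytest.approx(r_ranks)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1, 1, 1], [1, 2, 3])


class TestOptimizeCutoff:
    def test_planted_cutoff_recovered(self):
        builder, _ = simulate_planted_cutoff_cohort(n_patients=200, planted_cutoff=0.8, seed=7)
        best, aucs = optimize_editing_cutoff(builder)
        assert best == pytest.approx(0.8)
        assert len(aucs) == 11

    def test_null_signal_returns_smallest_grid_value(self):
        rng = np.random.default_rng(3)
        iotnl = rng.uniform(0, 10, 100)
        labels = np.where(rng.random(100) < 0.4, "ORR", "NOR")

        def builder(cut):
            # scores unrelated to outcome and identical at every cutoff
            return pd.DataFrame({"iotnl": iotnl, "orr_label": labels})

        best, aucs = optimize_editing_cutoff(builder)
        assert best == 0.5  # AUC ties resolve to the smallest cutoff
        assert np.allclose(list(aucs.values()), list(aucs.values())[0])

    def test_single_value_grid(self):
        builder, _ = simulate_planted_cutoff_cohort(n_patients=50, seed=1)
        best, aucs = optimize_editing_cutoff(builder, grid_start=1.0, grid_stop=1.0)
        assert best == 1.0 and list(aucs) == [1.0]


class TestEvaluateDichotomy:
    def test_ne_patients_dropped_from_response_kept_for_survival(self):
        rng = np.random.default_rng(8)
        n = 40
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "iotnl": rng.uniform(0, 5, n),
                "orr_label": ["NE"] * 4 + ["ORR", "NOR"] * 18,
                "pfs_days": rng.exponential(100, n),
                "pfs_event": rng.integers(0, 2, n),
            }
        )
        res = evaluate_dichotomy(df, time_col="pfs_days", event_col="pfs_event")
        assert res.metadata["n_enrolled"] == 40
        assert res.metadata["n_evaluable"] == 36
        assert res.n_high + res.n_low == 36
        assert res.logrank_p is not None
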