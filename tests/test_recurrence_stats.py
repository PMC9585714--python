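"""Group comparisons, ROC/DeLong, operating points, selection, CV, Cox, PR."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score, roc_curve

from sspkrecur import FirthLogit
from sspkrecur.recurrence import (
    backwards_stepwise_aic,
    cox_ph_univariable,
    delong_analysis,
    equal_variance_ttest,
    fisher_exact_test,
    pc1_of_metrics,
    precision_recall_points,
    repeated_kfold_cv_auc,
    roc_auc_mann_whitney,
    youden_operating_point,
)


class TestTTest:
    def test_identical_groups(self):
        t, p, df = equal_variance_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_hand_computed_pooled_variance(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([3.0, 4, 5, 6])
        sp2 = (3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t_hand), 6)
        t, p, df = equal_variance_ttest(x, y)
        assert t == pytest.approx(t_hand) and p == pytest.approx(p_hand) and df == 6

    def test_zero_variance_conventions(self):
        _, p, _ = equal_variance_ttest([2.0, 2, 2], [2.0, 2, 2])
        assert p == 1.0
        _, p, _ = equal_variance_ttest([2.0, 2, 2], [3.0, 3, 3])
        assert p == 0.0


class TestFisherExact:
    def test_proportional_rows(self):
        assert fisher_exact_test([[4, 8], [2, 4]]) == pytest.approx(1.0)

    def test_diagonal_table_full_enumeration(self):
        # only the two extreme tables are as or more extreme: p = 2 / C(10,5)
        assert fisher_exact_test([[5, 0], [0, 5]]) == pytest.approx(2 / comb(10, 5))

    def test_2xk_matches_enumeration_oracle(self):
        table = np.array([[12, 9, 16, 3], [0, 1, 2, 4]])
        cols = table.sum(axis=0)
        r1 = table[0].sum()
        n = cols.sum()

        def prob(a):
            return np.prod([comb(c, ai) for c, ai in zip(cols, a)]) / comb(n, r1)

        obs = prob(table[0])
        total = 0.0
        for a in itertools.product(*[range(c + 1) for c in cols]):
            if sum(a) == r1 and prob(a) <= obs * (1 + 1e-9):
                total += prob(a)
        assert fisher_exact_test(table) == pytest.approx(total, rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact_test([[0, 0], [3, 4]]) == 1.0


class TestROCAndDeLong:
    def test_perfect_separation(self):
        assert roc_auc_mann_whitney([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc_mann_whitney([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force_pairs_and_sklearn(self, rng):
        s = rng.normal(size=30)
        s[::3] = np.round(s[::3], 1)  # inject some ties
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        auc = roc_auc_mann_whitney(s, y)
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                         for p in pos for q in neg])
        assert auc == pytest.approx(brute)
        assert auc == pytest.approx(roc_auc_score(y, s))

    def test_auc_equals_trapezoid_roc_area(self, rng):
        for _ in range(5):
            s = rng.normal(size=40)
            y = rng.integers(0, 2, 40)
            y[:2] = [0, 1]
            fpr, tpr, _ = roc_curve(y, s)
            assert roc_auc_mann_whitney(s, y) == pytest.approx(np.trapezoid(tpr, fpr))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_mann_whitney([1.0, 2.0], [1, 1])

    def test_paired_self_comparison_is_null(self, rng):
        s = rng.normal(size=25)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        res = delong_analysis(s, y, s)
        assert res.z == 0.0 and res.pvalue == 1.0

    def test_ci_midpoint_is_auc(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = delong_analysis(s, y)
        if 0 < res.ci[0] and res.ci[1] < 1:  # unclipped Wald interval
            assert 0.5 * (res.ci[0] + res.ci[1]) == pytest.approx(res.auc)

    def test_variance_close_to_bootstrap(self, rng):
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        y[:2] = [0, 1]
        s = rng.normal(size=n) + 0.8 * y
        res = delong_analysis(s, y)
        boots = np.empty(10_000)
        for b in range(boots.size):
            idx = rng.integers(0, n, n)
            while len(np.unique(y[idx])) < 2:
                idx = rng.integers(0, n, n)
            boots[b] = roc_auc_mann_whitney(s[idx], y[idx])
        assert res.variance == pytest.approx(boots.var(ddof=1), rel=0.15)

    def test_degenerate_perfect_auc_flagged(self):
        res = delong_analysis([1, 2, 3, 9, 10], [0, 0, 0, 1, 1])
        assert res.degenerate


class TestYouden:
    def test_perfect_separation(self):
        op = youden_operating_point([1, 2, 3, 8, 9], [0, 0, 0, 1, 1])
        assert op.youden_j == pytest.approx(1.0)
        assert op.sensitivity == 1.0 and op.specificity == 1.0

    def test_uninformative_scores(self):
        op = youden_operating_point([2.0] * 8, [0, 1] * 4)
        assert op.youden_j == pytest.approx(0.0)

    def test_matches_exhaustive_grid(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        op = youden_operating_point(s, y)
        best_j = max(
            np.mean(s[y == 1] >= c) + np.mean(s[y == 0] < c) - 1.0
            for c in np.concatenate([s - 1e-9, s + 1e-9])
        )
        assert op.youden_j == pytest.approx(best_j, abs=1e-12)
        # dominance over every observed threshold
        for c in s:
            j = np.mean(s[y == 1] >= c) + np.mean(s[y == 0] < c) - 1.0
            assert op.youden_j >= j - 1e-12

    def test_exact_cis_contain_point_estimates(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        op = youden_operating_point(s, y)
        assert op.sensitivity_ci[0] <= op.sensitivity <= op.sensitivity_ci[1]
        assert op.specificity_ci[0] <= op.specificity <= op.specificity_ci[1]


class TestStepwise:
    def test_noise_candidate_dropped(self, rng):
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(1.0 - 1.5 * x1))).astype(int)
        df = pd.DataFrame({"y": y, "signal": x1, "noise": x2})
        selected, _ = backwards_stepwise_aic(df, "y", ["signal", "noise"])
        assert selected == ["signal"]

    def test_empty_candidates_intercept_only(self, rng):
        df = pd.DataFrame({"y": rng.integers(0, 2, 30)})
        selected, fit = backwards_stepwise_aic(df, "y", [])
        assert selected == []
        assert list(fit.params.index) == ["const"]

    def test_matches_exhaustive_subset_search(self, rng):
        n = 250
        X = rng.normal(size=(n, 4))
        y = (rng.random(n) < 1 / (1 + np.exp(0.5 - 1.2 * X[:, 0] + 0.9 * X[:, 2]))).astype(int)
        cols = ["a", "b", "c", "d"]
        df = pd.DataFrame(X, columns=cols)
        df["y"] = y
        selected, fit = backwards_stepwise_aic(df, "y", cols)
        best = None
        for k in range(5):
            for combo in itertools.combinations(cols, k):
                if combo:
                    f = FirthLogit.from_dataframe(df, "y", list(combo)).fit()
                else:
                    f = FirthLogit(y, np.empty((n, 0)), exog_names=[]).fit()
                if best is None or f.aic < best[0]:
                    best = (f.aic, set(combo))
        assert fit.aic == pytest.approx(best[0])
        assert set(selected) == best[1]


class TestCrossValidation:
    def test_null_predictor_calibrated(self):
        # a single draw has SD ~0.045, so the calibration of the estimator is
        # checked on the mean over independent null cohorts
        vals = []
        for ds in range(10):
            g = np.random.default_rng(100 + ds)
            x = g.normal(size=200)
            y = g.integers(0, 2, 200)
            vals.append(repeated_kfold_cv_auc(x, y, k=5, repeats=20, seed=7))
        assert 0.45 <= float(np.mean(vals)) <= 0.55

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.3).astype(int)
        y[:5] = 1
        a = repeated_kfold_cv_auc(x, y, k=5, repeats=10, seed=3)
        b = repeated_kfold_cv_auc(x, y, k=5, repeats=10, seed=3)
        assert a == b

    def test_optimism_of_apparent_auc(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-3.0 * x))).astype(int)
        fit = FirthLogit(y, x).fit()
        apparent = roc_auc_mann_whitney(fit.predict_linear(x[:, None]), y)
        cv = repeated_kfold_cv_auc(x, y, k=5, repeats=10, seed=1)
        assert cv <= apparent + 1e-9
        assert cv > 0.8

    def test_too_few_events_rejected(self):
        y = np.zeros(40, dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError, match="folds"):
            repeated_kfold_cv_auc(np.arange(40.0), y, k=5, repeats=2, seed=0)


class TestCox:
    def test_grid_search_oracle_no_ties(self):
        time = np.array([2.0, 3.5, 5.0, 6.1, 7.3, 9.0, 11.2, 14.0])
        event = np.ones(8, dtype=int)
        x = np.array([1.2, 0.8, 1.5, 0.3, 0.9, -0.2, 0.1, -1.0])
        hr, p, beta = cox_ph_univariable(time, event, x)

        def neg_pl(b):
            order = np.argsort(time)
            ll = 0.0
            for i in order:
                risk = time >= time[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -ll

        grid = np.linspace(beta - 0.5, beta + 0.5, 20001)
        best = grid[np.argmin([neg_pl(b) for b in grid])]
        assert beta == pytest.approx(best, abs=1e-4)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(10, 60)
        event = rng.integers(0, 2, 60)
        event[:3] = 1
        x = rng.normal(size=60)
        _, _, b1 = cox_ph_univariable(time, event, x)
        _, _, b2 = cox_ph_univariable(time * 30.44, event, x)
        assert b1 == pytest.approx(b2, abs=1e-8)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(11)
        n, reps = 300, 300
        rejections = 0
        for _ in range(reps):
            time = rng.exponential(10, n)
            event = rng.random(n) < 0.3
            x = rng.normal(size=n)
            _, p, _ = cox_ph_univariable(time, event.astype(int), x)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.08

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_ph_univariable([1.0, 2, 3, 4], [1, 1, 1, 0], [2.0, 2, 2, 2])


class TestPCA:
    def test_perfectly_correlated_pair(self, rng):
        a = rng.normal(size=50)
        df = pd.DataFrame({"m1": a, "ktrans_v4": 2 * a + 1})
        res = pc1_of_metrics(df)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        assert res.eigenvalues[1:] == pytest.approx(0.0, abs=1e-10)

    def test_eigenvalues_sum_to_column_count(self, rng):
        df = pd.DataFrame(rng.normal(size=(47, 13)))
        res = pc1_of_metrics(df, sign_column=None)
        assert res.eigenvalues.sum() == pytest.approx(13.0)

    def test_matches_power_iteration_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(47, 13)),
                          columns=[f"m{i}" for i in range(12)] + ["ktrans_v4"])
        res = pc1_of_metrics(df)
        z = (df - df.mean()) / df.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        v = np.ones(13) / np.sqrt(13)
        for _ in range(3000):
            v = corr @ v
            v /= np.linalg.norm(v)
        if v[list(df.columns).index("ktrans_v4")] < 0:
            v = -v
        assert np.allclose(res.scores.to_numpy(), z.to_numpy() @ v, atol=1e-6)

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=["a", "b", "c", "d", "ktrans_v4"])
        res = pc1_of_metrics(df)
        assert res.loadings.loc["ktrans_v4", "PC1"] > 0

    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30),
                           "c": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            res = pc1_of_metrics(df, sign_column=None)
        assert res.columns == ["a", "b"]


class TestPrecisionRecall:
    def test_perfect_classifier(self):
        *_, ap = precision_recall_points([1, 2, 3, 9, 10], [0, 0, 0, 1, 1])
        assert ap == 1.0

    def test_single_positive_ranked_first(self):
        *_, ap = precision_recall_points([0.1, 0.2, 0.9], [0, 0, 1])
        assert ap == 1.0

    def test_null_scores_ap_near_prevalence(self, rng):
        n = 2000
        y = (rng.random(n) < 0.15).astype(int)
        s = rng.normal(size=n)
        *_, ap = precision_recall_points(s, y)
        assert abs(ap - y.mean()) < 0.05
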