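"""Logistic regression, stepwise selection, RF importance, agreement stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

import mrdcyte as m
from mrdcyte.models import (
    RFConfig,
    _bootstrap_oob_masks,
    fit_logistic,
    forward_select,
    hosmer_lemeshow,
    score_test,
    train_rf_eval,
)
from mrdcyte.simulate import null_effect_profile


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        x = np.repeat([1, 1, 0, 0], [8, 2, 2, 8])
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.coefficients.loc["x", "B"] == pytest.approx(np.log(16),
                                                               abs=1e-6)
        assert fit.coefficients.loc["x", "OR"] == pytest.approx(16, rel=1e-5)

    def test_matches_direct_likelihood_maximizer(self):
        """Coefficients agree with an independent numerical maximizer of
        the Bernoulli log-likelihood on a 2-feature toy set."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        logits = 0.8 * X[:, 0] - 1.1 * X[:, 1] + 0.3
        y = rng.random(60) < 1 / (1 + np.exp(-logits))
        fit = fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y.astype(int))

        def nll(beta):
            eta = beta[0] + X @ beta[1:]
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        opt = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        assert fit.coefficients.loc["const", "B"] == pytest.approx(opt.x[0],
                                                                   abs=1e-4)
        assert fit.coefficients.loc["a", "B"] == pytest.approx(opt.x[1],
                                                               abs=1e-4)
        assert fit.coefficients.loc["b", "B"] == pytest.approx(opt.x[2],
                                                               abs=1e-4)

    def test_intercept_only_baseline(self):
        y = np.array([1] * 80 + [0] * 121)
        fit = fit_logistic(None, y)
        assert fit.fitted_probabilities[0] == pytest.approx(80 / 201)
        assert fit.accuracy == pytest.approx(100 * 121 / 201, abs=1e-9)
        assert fit.sensitivity == 0.0 and fit.specificity == 100.0

    def test_wald_or_ci_invariants(self, default_cohort):
        fit = fit_logistic(default_cohort.drop(columns=["MRD"]),
                           default_cohort["MRD"])
        c = fit.coefficients
        np.testing.assert_allclose(c["Wald"], (c["B"] / c["SE"]) ** 2)
        np.testing.assert_allclose(c["OR"], np.exp(c["B"]))
        np.testing.assert_allclose(c["CI_low"],
                                   np.exp(c["B"] - 1.96 * c["SE"]))

    def test_null_slope_p_values_uniform(self):
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            y = rng.integers(0, 2, 200)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            pvals.append(fit.coefficients.loc["x", "p"])
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= frac <= 0.12

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not fit.converged

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_logistic(None, np.ones(20))  # single class
        with pytest.raises(ValueError):
            fit_logistic(None, np.r_[np.ones(3), np.zeros(3)])  # n < 10


class TestNagelkerke:
    def test_null_equals_zero(self):
        assert m.nagelkerke_r2(-100.0, -100.0, 150) == 0.0

    def test_saturated_equals_one(self):
        ll_null = 200 * np.log(0.5)  # balanced labels
        assert m.nagelkerke_r2(ll_null, 0.0, 200) == pytest.approx(1.0)

    def test_matches_independent_formula(self, default_cohort):
        fit = fit_logistic(default_cohort.drop(columns=["MRD"]),
                           default_cohort["MRD"])
        n = fit.n
        r2_cs = 1 - np.exp(2 * (fit.ll_null - fit.ll) / n)
        expected = r2_cs / (1 - np.exp(2 * fit.ll_null / n))
        assert fit.nagelkerke == pytest.approx(expected, rel=1e-10)


class TestForwardSelection:
    def test_uninformative_features_yield_empty_path(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({"flat": np.zeros(100)})
        path = forward_select(X, y)
        assert path.entry_order == []

    def test_dominant_feature_enters_first(self):
        firsts = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            y = rng.integers(0, 2, n)
            X = pd.DataFrame({
                "signal": y * 3.0 + rng.normal(size=n),
                **{f"noise{i}": rng.normal(size=n) for i in range(4)},
            })
            path = forward_select(X, y)
            firsts += path.entry_order[:1] == ["signal"]
        assert firsts == 20

    def test_minus2ll_non_increasing_along_path(self, default_cohort):
        path = forward_select(default_cohort.drop(columns=["MRD"]),
                              default_cohort["MRD"])
        lls = path.minus2ll_path
        assert all(b <= a + 1e-8 for a, b in zip(lls, lls[1:]))

    def test_reported_ordering_structure_recovered(self):
        """The strong markers of the patient-level model (CD304, CD73,
        CD58) enter before the negligible ones (CD99, CD86, CD22) in a
        clear majority of simulated cohorts."""
        ok = 0
        n_seeds = 30
        strong, weak = {"CD304", "CD73", "CD58"}, {"CD99", "CD86", "CD22"}
        for seed in range(n_seeds):
            cohort = m.simulate_cohort(m.CohortConfig(seed=seed))
            order = forward_select(cohort.drop(columns=["MRD"]),
                                   cohort["MRD"]).entry_order
            pos = {v: i for i, v in enumerate(order)}
            entered_weak = weak & set(order)
            ok += strong <= set(order) and (
                not entered_weak
                or max(pos[v] for v in strong) < min(pos[v] for v in entered_weak))
        assert ok > n_seeds / 2

    def test_score_test_matches_wald_asymptotics(self, default_cohort):
        """Score and Wald chi-squares agree to leading order for a
        moderately informative candidate."""
        X = default_cohort.drop(columns=["MRD"])
        y = default_cohort["MRD"]
        chi2_score, _ = score_test(X, y, ("CD304",), "CD44")
        fit = fit_logistic(X, y, variables=("CD304", "CD44"))
        chi2_wald = fit.coefficients.loc["CD44", "Wald"]
        assert chi2_score == pytest.approx(chi2_wald, rel=0.5)


class TestHosmerLemeshow:
    def test_minimum_groups_df(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        y = (rng.random(30) < p).astype(int)
        hl = hosmer_lemeshow(p, y, g=3)
        assert hl.df == 1

    def test_calibrated_probabilities_fit_well(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.random(500)
            y = (rng.random(500) < p).astype(int)
            rejections += hosmer_lemeshow(p, y).p < 0.05
        assert rejections <= 4

    def test_constant_probabilities_degenerate(self):
        hl = hosmer_lemeshow(np.full(50, 0.4),
                             np.r_[np.ones(20), np.zeros(30)])
        assert hl.degenerate
        assert np.isnan(hl.p)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 50, [0] * 50, g=2)
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [0] * 5, g=10)


class TestAgreementStatistics:
    def test_kappa_reported_matrix(self):
        assert m.cohen_kappa(21, 3, 1, 35) == pytest.approx(0.8592, abs=5e-5)

    def test_kappa_perfect_and_chance(self):
        assert m.cohen_kappa(30, 0, 0, 30) == 1.0
        assert m.cohen_kappa(10, 10, 10, 10) == 0.0

    def test_kappa_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(7)
        for _ in range(300):
            tp, fn, fp, tn = rng.integers(1, 30, 4)
            y_true = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            y_pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp),
                           np.zeros(tn)]
            assert m.cohen_kappa(tp, fn, fp, tn) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)

    @pytest.mark.parametrize("b,c,chi2,p", [
        (3, 1, 0.25, 0.6171),
        (7, 7, 0.0, 1.0),
        (10, 0, 8.1, 0.0044),
    ])
    def test_mcnemar_examples(self, b, c, chi2, p):
        got_chi2, got_p = m.mcnemar_cc(b, c)
        assert got_chi2 == pytest.approx(chi2, abs=1e-9)
        assert got_p == pytest.approx(p, abs=5e-5)

    def test_mcnemar_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar
        rng = np.random.default_rng(9)
        for _ in range(200):
            b, c = rng.integers(2, 40, 2)
            if abs(int(b) - int(c)) <= 1:
                # our correction is clamped at zero there by design
                continue
            table = [[5, b], [c, 5]]
            ref = mcnemar(table, exact=False, correction=True)
            got_chi2, got_p = m.mcnemar_cc(b, c)
            assert got_chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert got_p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_clopper_pearson_bounds(self):
        assert m.clopper_pearson(0, 10) == (0.0, pytest.approx(0.3085, abs=1e-3))
        assert m.clopper_pearson(10, 10)[1] == 1.0
        lo, hi = m.clopper_pearson(56, 60)
        assert lo == pytest.approx(0.838, abs=5e-4)
        assert hi == pytest.approx(0.9815, abs=5e-5)

    def test_clopper_pearson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = m.clopper_pearson(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)


class TestRandomForest:
    def test_seeded_determinism(self, default_cohort):
        imp1, ev1 = train_rf_eval(default_cohort, RFConfig(seed=5))
        imp2, ev2 = train_rf_eval(default_cohort, RFConfig(seed=5))
        pd.testing.assert_frame_equal(imp1, imp2)
        assert ev1 == ev2

    def test_oob_replication_matches_sklearn(self, default_cohort):
        """Our reconstruction of each tree's bootstrap draw reproduces
        sklearn's own OOB decision function exactly."""
        from sklearn.ensemble import RandomForestClassifier
        X = default_cohort.drop(columns=["MRD"]).to_numpy()
        y = default_cohort["MRD"].to_numpy()
        forest = RandomForestClassifier(40, oob_score=True, random_state=3,
                                        max_features=4).fit(X, y)
        votes = np.zeros((len(y), 2))
        hits = np.zeros(len(y))
        for est, oob in _bootstrap_oob_masks(forest, len(y)):
            votes[oob] += est.predict_proba(X[oob])
            hits[oob] += 1
        mask = hits > 0
        mine = votes[mask] / hits[mask, None]
        np.testing.assert_allclose(mine, forest.oob_decision_function_[mask])

    def test_noise_features_have_near_zero_mda(self):
        cohort = m.simulate_cohort(m.CohortConfig(
            n_samples=300, seed=21, effect_profile=null_effect_profile()))
        importance, _ = train_rf_eval(cohort, RFConfig(seed=21))
        assert np.abs(importance["MDA"]).max() < 2.0  # percentage points

    def test_informative_cohort_importance_ranking(self):
        """CD304, CD73 and CD58 take the top-3 MDA ranks in a majority
        of cohorts simulated under the reported model structure."""
        top3_ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cohort = m.simulate_cohort(m.CohortConfig(seed=seed))
            importance, _ = train_rf_eval(cohort, RFConfig(seed=seed))
            top3_ok += set(importance["MDA"].nlargest(3).index) == \
                {"CD304", "CD73", "CD58"}
        assert top3_ok > n_seeds / 2

    def test_mdg_nonnegative_and_gini_consistent(self, default_cohort):
        importance, _ = train_rf_eval(default_cohort, RFConfig(seed=1))
        assert (importance["MDG"] >= 0).all()
        # cross-check the node-walk against sklearn's own per-tree
        # unnormalized impurity-decrease computation
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import train_test_split
        X = default_cohort.drop(columns=["MRD"])
        y = default_cohort["MRD"].to_numpy()
        Xtr, _, ytr, _ = train_test_split(X.to_numpy(float), y,
                                          train_size=0.7, stratify=y,
                                          random_state=1)
        forest = RandomForestClassifier(100, max_features=4, oob_score=True,
                                        random_state=1).fit(Xtr, ytr)
        expected = np.mean(
            [est.tree_.compute_feature_importances(normalize=False)
             for est in forest.estimators_], axis=0) * len(Xtr)
        np.testing.assert_allclose(importance["MDG"].to_numpy(), expected,
                                   rtol=1e-8)

    def test_degenerate_split_rejected(self):
        cohort = pd.DataFrame({"x": np.arange(10.0),
                               "MRD": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]})
        with pytest.raises(ValueError):
            train_rf_eval(cohort, RFConfig(seed=0))

    def test_cross_validated_evaluation(self, default_cohort):
        importance, ev = train_rf_eval(default_cohort,
                                       RFConfig(seed=2, cv_folds=5))
        assert ev.tp + ev.fn + ev.fp + ev.tn == len(default_cohort)
        assert 0.5 < ev.accuracy <= 1.0
        assert set(importance.index) == set(m.STUDY_MARKERS)

    def test_mtry_validation(self, default_cohort):
        with pytest.raises(ValueError):
            train_rf_eval(default_cohort, RFConfig(mtry=99, seed=0))
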