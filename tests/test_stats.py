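"""Summary statistics, nonparametric comparisons, ROC threshold discovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import mrdcyte as m
from mrdcyte.stats import ThresholdMetrics, YoudenThreshold


class TestSummarize:
    def test_even_n_median_midpoint(self):
        s = m.summarize([1, 2, 3, 4])
        assert s.median == 2.5
        assert s.iqr == pytest.approx(1.5)  # type-7 linear interpolation

    def test_constant_vector(self):
        s = m.summarize([7.0] * 10)
        assert s.iqr == 0.0 and s.sd == 0.0

    def test_hand_computed_sd(self):
        s = m.summarize([2, 4, 4, 4, 5, 5, 7, 9])
        assert s.sd == pytest.approx(np.sqrt(32 / 7), abs=1e-3)
        assert s.mean == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.summarize([])


class TestShapiroWilk:
    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            m.shapiro_wilk([1.0, 2.0])

    def test_exact_normal_quantiles_pass(self):
        x = sps.norm.ppf((np.arange(50) + 0.5) / 50)
        _, p = m.shapiro_wilk(x)
        assert p > 0.05

    def test_exponential_samples_rejected(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).exponential(size=100)
            rejections += m.shapiro_wilk(x)[1] < 0.05
        assert rejections >= 38  # >= 95% of seeds


class TestKruskalWallis:
    def test_identical_values_give_zero_h(self):
        r = m.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert r.h == 0.0 and r.p == 1.0

    def test_hand_computed_h(self):
        r = m.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert r.h == pytest.approx(3.857, abs=1e-3)

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=30)
            pvals.append(m.kruskal_wallis([x[:10], x[10:20], x[20:]]).p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.01 <= frac <= 0.10

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            m.kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            m.kruskal_wallis([[1.0], [2.0]])  # total n < 3


class TestDunnBonferroni:
    def test_two_groups_single_pair_unadjusted(self):
        a, b = [1.0, 2.0, 5.0], [3.0, 8.0, 9.0, 10.0]
        table = m.pairwise_bonferroni([a, b])
        # independent hand computation of Dunn's z for one pair, no ties
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        r1, r2 = ranks[:3].mean(), ranks[3:].mean()
        n = len(pooled)
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 4))
        expected = 2 * sps.norm.sf(abs((r1 - r2) / se))
        assert table.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_identical_data_all_ones(self):
        table = m.pairwise_bonferroni([[1.0, 1.0]] * 3)
        assert (table.to_numpy() == 1.0).all()

    def test_extreme_pair_has_smallest_adjusted_p(self):
        groups = {"low": np.arange(10.0), "mid": np.arange(10.0) + 6,
                  "high": np.arange(10.0) + 12}
        table = m.pairwise_bonferroni(groups)
        assert table.loc["low", "high"] == table.to_numpy().min()

    def test_symmetry_and_range(self, default_cohort):
        y = default_cohort["MRD"]
        groups = {"neg": default_cohort.loc[y == 0, "CD73"],
                  "pos": default_cohort.loc[y == 1, "CD73"]}
        table = m.pairwise_bonferroni(groups)
        assert (table.to_numpy() == table.to_numpy().T).all()
        assert ((table.to_numpy() >= 0) & (table.to_numpy() <= 1)).all()


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_best(pos, neg):
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    pooled = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([[pooled[0] - 1],
                            (pooled[:-1] + pooled[1:]) / 2,
                            [pooled[-1] + 1]])
    best = None
    for t in cands:
        sens = (pos > t).mean()
        spec = (neg <= t).mean()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, spec, t)
        elif abs(j - best[0]) <= 1e-12 and (spec, t) > (best[1], best[2]):
            best = (j, spec, t)
    return best


class TestROC:
    def test_complete_ties_give_half(self):
        x = [1.0, 2.0, 3.0]
        assert m.roc_auc(x, x).auc == 0.5

    def test_full_separation(self):
        assert m.roc_auc([10, 11], [1, 2, 3]).auc == 1.0

    def test_pair_counting_example(self):
        assert m.roc_auc([3, 5], [1, 2, 4]).auc == pytest.approx(5 / 6)

    def test_label_swap_complement(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 40)
        assert m.roc_auc(a, b).auc == pytest.approx(1 - m.roc_auc(b, a).auc)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
        base = m.roc_auc(a, b).auc
        assert m.roc_auc(np.exp(a), np.exp(b)).auc == pytest.approx(base)
        assert m.roc_auc(3 * a - 7, 3 * b - 7).auc == pytest.approx(base)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        y = np.r_[np.ones(50), np.zeros(60)]
        assert m.roc_auc(a, b).auc == pytest.approx(
            roc_auc_score(y, np.r_[a, b]))


class TestBestThreshold:
    def test_full_separation_perfect_metrics(self):
        mt = m.best_threshold(m.roc_auc([10.0, 11.0], [1.0, 2.0]))
        assert mt.sensitivity == 100.0 and mt.specificity == 100.0
        assert 2.0 < mt.threshold < 10.0
        assert mt.youden == pytest.approx(1.0)

    def test_small_example_scan(self):
        mt = m.best_threshold(m.roc_auc([3.0, 5.0], [1.0, 2.0, 4.0]))
        assert 2.0 < mt.threshold < 3.0
        assert mt.sensitivity == 100.0
        assert mt.specificity == pytest.approx(200 / 3, abs=0.01)

    def test_single_observation_each(self):
        mt = m.best_threshold(m.roc_auc([5.0], [2.0]))
        assert mt.sensitivity == 100.0 and mt.specificity == 100.0

    def test_matches_exhaustive_scan(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pos = rng.integers(0, 20, rng.integers(2, 30)).astype(float)
            neg = rng.integers(0, 20, rng.integers(2, 30)).astype(float)
            mt = m.best_threshold(m.roc_auc(pos, neg))
            j, spec, t = brute_force_best(pos, neg)
            assert mt.youden == pytest.approx(j, abs=1e-9)
            assert mt.threshold == pytest.approx(t)


class TestConfusionMetrics:
    @pytest.mark.parametrize("counts,sens,spec,ppv,npv", [
        ((18, 4, 15, 5), 81.8, 75.0, 78.3, 78.9),
        ((118, 3, 16, 4), 97.5, 80.0, 96.7, 84.2),
        ((20, 0, 20, 0), 100.0, 100.0, 100.0, 100.0),
    ])
    def test_rate_reports(self, counts, sens, spec, ppv, npv):
        rep = m.confusion_metrics(*counts).report()
        assert (rep["sensitivity"], rep["specificity"]) == (sens, spec)
        assert (rep["PPV"], rep["NPV"]) == (ppv, npv)

    def test_undefined_ppv_is_absent(self):
        mt = m.confusion_metrics(0, 5, 3, 0)
        assert mt.ppv is None
        assert mt.report()["PPV"] is None

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            m.confusion_metrics(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            m.confusion_metrics(0, 0, 1, 1)


class TestYoudenEstimator:
    def test_fit_predict_round_trip(self, default_cohort):
        y = default_cohort["MRD"].to_numpy()
        x = default_cohort[["CD73"]].to_numpy()
        est = YoudenThreshold().fit(x, y)
        pred = est.predict(x)
        assert set(pred) <= set(est.classes_)
        agreement = (pred == y).mean()
        assert agreement > 0.7  # CD73 is strongly informative by design
        assert isinstance(est.metrics_, ThresholdMetrics)

    def test_requires_single_feature(self):
        with pytest.raises(ValueError):
            YoudenThreshold().fit(np.zeros((10, 2)), np.r_[np.ones(5),
                                                           np.zeros(5)])
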