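import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from gliodti import (
    CohortSpec,
    group_compare,
    kappa_band,
    ppv_from_confusion,
    roc_analysis,
    simulate_cohort,
    weighted_kappa,
)


def concordance_auc(values, labels):
    """Brute-force Mann-Whitney concordance with half credit for ties.

    With low-is-positive scoring, a transformed/stable pair is
    concordant when the transformed value is the smaller one.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels)
    pos = v[y == 1]
    neg = v[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a < b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


class TestROC:
    def test_perfect_separation(self):
        v = np.array([0.5, 0.6, 0.7, 1.1, 1.2, 1.3])
        y = np.array([1, 1, 1, 0, 0, 0])
        r = roc_analysis(v, y)
        assert r.auc == pytest.approx(1.0)
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert 0.7 < r.cutoff < 1.1

    def test_six_value_example_cutoff_between_clusters(self):
        v = np.array([0.5, 0.7, 0.9, 1.1, 1.3, 1.5])
        y = np.array([1, 1, 1, 0, 0, 0])
        r = roc_analysis(v, y)
        assert r.auc == pytest.approx(concordance_auc(v, y))  # 9/9 concordant
        assert 0.9 < r.cutoff < 1.1

    def test_exhaustive_labelings_of_eight_values(self):
        rng = np.random.default_rng(123)
        v = rng.random(8)
        for pos_idx in itertools.combinations(range(8), 3):  # all 56 labelings
            y = np.zeros(8, int)
            y[list(pos_idx)] = 1
            r = roc_analysis(v, y)
            assert r.auc == pytest.approx(concordance_auc(v, y), abs=1e-12)

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            v = np.round(rng.random(n), 2)  # coarse values force ties
            y = np.zeros(n, int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            r = roc_analysis(v, y)
            assert r.auc == pytest.approx(concordance_auc(v, y), abs=1e-12)

    def test_agrees_with_sklearn_oracle(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        v = rng.random(40)
        y = rng.integers(0, 2, 40)
        r = roc_analysis(v, y)
        assert r.auc == pytest.approx(sklearn_metrics.roc_auc_score(y, -v), abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        v = rng.random(20)
        y = np.array([1] * 8 + [0] * 12)
        a = roc_analysis(v, y)
        b = roc_analysis(v * scale, y)
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        assert b.sensitivity == a.sensitivity and b.specificity == a.specificity
        assert b.cutoff == pytest.approx(a.cutoff * scale, rel=1e-9)

    def test_reversed_direction_complements_auc(self):
        # scoring the negated values flips the positivity direction
        rng = np.random.default_rng(5)
        v = rng.random(25)
        y = np.array([1] * 10 + [0] * 15)
        assert roc_analysis(-v, y).auc == pytest.approx(1.0 - roc_analysis(v, y).auc, abs=1e-12)

    def test_confusion_counts_are_consistent(self):
        rng = np.random.default_rng(9)
        v = rng.random(30)
        y = np.array([1] * 12 + [0] * 18)
        r = roc_analysis(v, y)
        tp, fp, tn, fn = r.confusion
        assert tp + fn == 12 and tn + fp == 18
        assert r.sensitivity == pytest.approx(100 * tp / (tp + fn), abs=0.1)
        assert r.specificity == pytest.approx(100 * tn / (tn + fp), abs=0.1)
        assert r.ppv == pytest.approx(100 * tp / (tp + fp), abs=0.1)

    def test_binormal_limit_of_the_cohort_generator(self):
        # 10k/group AD cohort: empirical AUC approaches the closed form
        # Phi(dmu / sqrt(s1^2 + s2^2)) of the generating normals
        table = simulate_cohort(CohortSpec(n_stable=10_000, n_transformed=10_000, seed=17))
        r = roc_analysis(table["ad_min"].to_numpy(), table["label"].to_numpy())
        closed = sps.norm.cdf((1.28 - 0.72) / np.hypot(0.31, 0.23))
        assert r.auc == pytest.approx(closed, abs=0.01)

    def test_single_class_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_analysis([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="finite"):
            roc_analysis([1.0, np.nan], [1, 0])

    def test_hanley_mcneil_se_positive_and_small_for_good_auc(self):
        v = np.array([0.5, 0.6, 0.7, 1.1, 1.2, 1.3])
        y = np.array([1, 1, 1, 0, 0, 0])
        r = roc_analysis(v, y)
        assert r.auc_se == 0.0  # AUC = 1 has zero Hanley-McNeil variance
        rng = np.random.default_rng(3)
        r2 = roc_analysis(rng.random(30), np.array([1] * 10 + [0] * 20))
        assert 0 < r2.auc_se < 0.2


class TestPPV:
    @pytest.mark.parametrize(
        "confusion, expected",
        [((17, 4, 25, 1), 100 * 17 / 21), ((5, 0, 9, 2), 100.0), ((7, 7, 3, 3), 50.0)],
    )
    def test_from_counts(self, confusion, expected):
        assert ppv_from_confusion(confusion) == pytest.approx(expected)

    def test_undefined_without_positive_tests(self):
        with pytest.raises(ValueError, match="undefined"):
            ppv_from_confusion((0, 0, 5, 5))


class TestWeightedKappa:
    def test_perfect_agreement(self):
        r = weighted_kappa([0, 1, 0, 1, 1], [0, 1, 0, 1, 1])
        assert r.kappa == pytest.approx(1.0)
        assert r.band_label == "substantial"

    def test_hand_computed_binary_table(self):
        # counts ((20,5),(5,20)): p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        r1 = [0] * 25 + [1] * 25
        r2 = [0] * 20 + [1] * 5 + [0] * 5 + [1] * 20
        r = weighted_kappa(r1, r2)
        assert r.kappa == pytest.approx(0.6)
        np.testing.assert_array_equal(r.contingency, [[20, 5], [5, 20]])

    def test_binary_weighting_schemes_coincide(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        lin = weighted_kappa(a, b, "linear").kappa
        quad = weighted_kappa(a, b, "quadratic").kappa
        assert lin == pytest.approx(quad, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(99)
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert abs(weighted_kappa(a, b).kappa) < 0.05

    def test_agrees_with_sklearn_oracle(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 4, 200))
        for w in ("linear", "quadratic"):
            ours = weighted_kappa(a, b, w).kappa
            theirs = sklearn_metrics.cohen_kappa_score(a, b, weights=w)
            assert ours == pytest.approx(theirs, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_rater_symmetry_and_tandem_permutation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
            return
        k1 = weighted_kappa(a, b).kappa
        assert weighted_kappa(b, a).kappa == pytest.approx(k1, abs=1e-12)
        perm = rng.permutation(50)
        assert weighted_kappa(a[perm], b[perm]).kappa == pytest.approx(k1, abs=1e-12)

    @pytest.mark.parametrize(
        "kappa, band",
        [(0.05, "slight"), (0.20, "slight"), (0.21, "fair"), (0.40, "fair"),
         (0.41, "moderate"), (0.60, "moderate"), (0.61, "very good"),
         (0.80, "very good"), (0.81, "substantial"), (1.0, "substantial")],
    )
    def test_band_edges(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_kappa([0, 0, 0, 0], [0, 0, 0, 0])


class TestGroupCompare:
    @staticmethod
    def cohort_from(x0, x1):
        n0, n1 = len(x0), len(x1)
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n0 + n1)],
                "label": [0] * n0 + [1] * n1,
                "ad_min": np.concatenate([x0, x1]),
                "md_min": np.concatenate([x0, x1]),
                "rd_min": np.concatenate([x0, x1]),
            }
        )

    def test_identical_group_distributions_give_zero_f(self):
        x = np.array([1.0, 1.2, 0.9, 1.1])
        g = group_compare(self.cohort_from(x, x))[0]
        assert g.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert g.p_raw == pytest.approx(1.0)
        assert g.p_bonferroni == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_f_equals_pooled_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        x0 = rng.normal(1.28, 0.31, 29)
        x1 = rng.normal(0.72, 0.23, 18)
        g = group_compare(self.cohort_from(x0, x1))[0]
        t, p = sps.ttest_ind(x0, x1, equal_var=True)
        assert g.f_statistic == pytest.approx(t**2, abs=1e-10)
        assert g.p_raw == pytest.approx(p, abs=1e-12)
        assert g.p_bonferroni == pytest.approx(min(1.0, 3 * p))

    def test_table_layout_fields(self):
        table = simulate_cohort(CohortSpec(seed=2))
        for g in group_compare(table):
            assert g.ci_stable[0] < g.mean_stable < g.ci_stable[1]
            assert g.ci_transformed[0] < g.mean_transformed < g.ci_transformed[1]
            assert g.f_statistic >= 0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            group_compare(self.cohort_from([1.0, 1.0], [1.0, 1.0]))

    def test_table3_conditions_yield_large_f(self):
        # replicated 29-vs-18 cohorts from the group distributions give
        # overwhelming significance, consistent with the reported F range
        fs, sig = [], 0
        for rep in range(200):
            table = simulate_cohort(CohortSpec(seed=10_000 + rep))
            g = group_compare(table)[0]
            fs.append(g.f_statistic)
            sig += g.p_bonferroni < 1e-4
        assert np.median(fs) > 10
        assert sig / 200 > 0.95
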