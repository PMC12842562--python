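import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdsirt.roc import (
    auc,
    chisq_two_proportions,
    cutoff_table,
    delong_paired,
    hanley_mcneil_independent,
    mcnemar,
    predictive_values,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(labels) == 1]
    controls = scores[np.asarray(labels) == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAuc:
    def test_worked_examples(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert auc([3, 1, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_constant_scores_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            r = auc([2, 2, 2, 2], [0, 0, 1, 1])
        assert r.auc == 0.5 and r.var == 0.0 and r.degenerate

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_matches_pair_counting_exhaustively(self):
        """Placement-value AUC equals brute-force pair counting on every
        random instance up to n=12 (including heavy ties)."""
        rng = np.random.default_rng(17)
        for _ in range(400):
            n = rng.integers(3, 13)
            n_cases = rng.integers(1, n)
            labels = np.zeros(n, int)
            labels[:n_cases] = 1
            scores = rng.integers(0, 4, n).astype(float)
            if len(np.unique(scores)) == 1:
                continue
            assert auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(18)
        labels = np.repeat([1, 0], [40, 160])
        scores = rng.normal(size=200) + labels
        assert auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_se_shrinks_like_inverse_sqrt_n(self):
        """DeLong SE on r-fold replicated data scales as 1/sqrt(r)."""
        rng = np.random.default_rng(19)
        labels = np.repeat([1, 0], [30, 170])
        scores = rng.normal(size=200) + labels * 1.2
        ses = []
        reps = [1, 4, 16]
        for r in reps:
            ses.append(auc(np.tile(scores, r), np.tile(labels, r)).se)
        slope = np.polyfit(np.log(reps), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_matches_proc_reference_values(self):
        """Frozen cross-check against R pROC (DeLong CI) on a fixed draw."""
        rng = np.random.default_rng(42)
        n = 40
        labels = np.array([1] * 8 + [0] * 32)
        theta = labels * 1.2 + rng.normal(size=n)
        s_a = np.round(theta + rng.normal(size=n) * 0.8, 3)
        s_b = np.round(theta + rng.normal(size=n) * 1.2, 3)
        r = auc(s_a, labels)
        assert r.auc == pytest.approx(0.765625, abs=1e-9)
        assert r.ci[0] == pytest.approx(0.5483105, abs=1e-6)
        assert r.ci[1] == pytest.approx(0.9829395, abs=1e-6)
        d = delong_paired(s_a, s_b, labels)
        assert d.delta_auc == pytest.approx(0.0859375, abs=1e-9)
        assert d.z == pytest.approx(1.164762, abs=1e-5)
        assert d.p == pytest.approx(0.2441154, abs=1e-6)


class TestDelongPaired:
    def test_identical_scores(self):
        r = delong_paired([1, 2, 3, 4], [1, 2, 3, 4], [0, 0, 1, 1])
        assert r.delta_auc == 0.0 and r.p == 1.0 and r.degenerate

    def test_antisymmetry(self):
        rng = np.random.default_rng(23)
        labels = np.repeat([1, 0], [20, 80])
        a = rng.normal(size=100) + labels
        b = rng.normal(size=100) + 0.5 * labels
        ab, ba = delong_paired(a, b, labels), delong_paired(b, a, labels)
        assert ab.delta_auc == pytest.approx(-ba.delta_auc)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_variance_close_to_bootstrap_oracle(self):
        """Resampling-subjects bootstrap of the AUC difference reproduces
        the analytic DeLong variance on a moderate instance."""
        rng = np.random.default_rng(29)
        labels = np.repeat([1, 0], [60, 240])
        a = rng.normal(size=300) + labels * 1.0
        b = rng.normal(size=300) + labels * 0.6
        analytic = delong_paired(a, b, labels).var
        diffs = []
        for _ in range(3000):
            idx = rng.integers(0, 300, 300)
            if labels[idx].sum() in (0, 300):
                continue
            diffs.append(
                brute_free_delta(a[idx], b[idx], labels[idx])
            )
        assert np.var(diffs) == pytest.approx(analytic, rel=0.15)


def brute_free_delta(a, b, labels):
    return auc(a, labels).auc - auc(b, labels).auc


class TestHanleyMcNeil:
    def test_equal_aucs(self):
        z, p = hanley_mcneil_independent(0.85, 0.02, 0.85, 0.02)
        assert z == 0.0 and p == 1.0

    def test_large_difference(self):
        se = 0.01
        z, p = hanley_mcneil_independent(0.9, se, 0.9 - 5 * np.sqrt(2) * se, se)
        assert p < 1e-5

    def test_zero_ses_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_independent(0.8, 0.0, 0.7, 0.0)


class TestYouden:
    def test_perfect_separation(self):
        c = youden_cutoff([0, 1, 2, 3], [0, 0, 1, 1])
        assert (c.cutoff, c.sensitivity, c.specificity) == (2.0, 100.0, 100.0)
        assert c.youden_j == pytest.approx(1.0)

    def test_labels_defined_by_threshold(self):
        scores = np.arange(10)
        labels = (scores >= 4).astype(int)
        c = youden_cutoff(scores, labels)
        assert c.cutoff == 4.0 and c.youden_j == pytest.approx(1.0)

    def test_j_nonnegative_on_random_scores(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            scores = rng.integers(0, 10, 50)
            labels = rng.integers(0, 2, 50)
            if labels.sum() in (0, 50):
                continue
            assert youden_cutoff(scores, labels).youden_j >= 0

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            return
        c1 = youden_cutoff(scores, labels)
        transformed = np.exp(scores / 3.0)
        c2 = youden_cutoff(transformed, labels)
        assert c2.youden_j == pytest.approx(c1.youden_j)
        assert c2.cutoff == pytest.approx(np.exp(c1.cutoff / 3.0))


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = [True] * 10 + [False] * 10
        b = [False] * 10 + [True] * 10
        assert mcnemar(a, b) == pytest.approx(1.0)

    def test_one_sided_discordance_exact(self):
        a = [True] * 20
        b = [False] * 20
        assert mcnemar(a, b) == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_no_discordance(self):
        assert mcnemar([True, False], [True, False]) == 1.0

    def test_matches_statsmodels_large_counts(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm

        a = np.array([True] * 40 + [False] * 25 + [True] * 100)
        b = np.array([False] * 40 + [True] * 25 + [True] * 100)
        expected = sm([[0, 40], [25, 0]], exact=False, correction=True).pvalue
        assert mcnemar(a, b) == pytest.approx(expected)


class TestChisqAndPredictiveValues:
    def test_identical_proportions(self):
        assert chisq_two_proportions(30, 100, 30, 100) == pytest.approx(1.0)

    def test_strong_difference(self):
        assert chisq_two_proportions(80, 100, 20, 100) < 1e-10

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning, match="margin"):
            assert chisq_two_proportions(100, 100, 50, 50) == 1.0

    def test_perfect_test(self):
        assert predictive_values(1.0, 1.0, 0.3) == (1.0, 1.0)

    def test_clinic_prevalence_ppv(self):
        ppv, _ = predictive_values(0.80, 0.84, 0.20)
        assert ppv == pytest.approx(0.5556, abs=5e-4)

    def test_community_prevalence_npv(self):
        _, npv = predictive_values(0.80, 0.84, 0.038)
        assert npv == pytest.approx(0.9907, abs=5e-4)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.8, 0.1)


def test_cutoff_table_columns_and_monotone_sens():
    rng = np.random.default_rng(37)
    labels = np.repeat([1, 0], [30, 270])
    scores = rng.integers(0, 11, 300) + labels * 3
    tab = cutoff_table(scores, labels)
    assert {"cutoff", "sensitivity", "specificity", "youden_j"} <= set(tab.columns)
    assert (np.diff(tab["sensitivity"]) <= 1e-9).all()  # sens falls as t rises
    assert (np.diff(tab["specificity"]) >= -1e-9).all()
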