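import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdsirt.banks import ItemBank, ScaleDefinition
from gdsirt.irt import (
    LatentGrid,
    TwoPLModel,
    cronbach_alpha,
    expected_test_information,
    icc,
    item_auc,
    item_information,
    rank_items,
)
from gdsirt.simulate import CohortConfig, generate_cohort


class TestIcc:
    def test_difficulty_is_the_half_endorsement_point(self):
        assert icc(0.60, a=2.47, b=0.60) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # 1 / (1 + e^{1.70 * 0.83})
        assert icc(0.0, a=1.70, b=0.83) == pytest.approx(0.196076, abs=1e-6)

    def test_logistic_limits(self):
        assert icc(50.0, a=1.3, b=2.0) == pytest.approx(1.0)
        assert icc(-50.0, a=1.3, b=2.0) == pytest.approx(0.0)

    def test_rejects_nonpositive_discrimination(self):
        with pytest.raises(ValueError):
            icc(0.0, a=0.0, b=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        theta=st.floats(-4, 4),
        a=st.floats(0.1, 5),
        b=st.floats(-3, 3),
        eps=st.floats(1e-3, 0.5),
    )
    def test_strictly_increasing_in_theta(self, theta, a, b, eps):
        assert icc(theta + eps, a, b) > icc(theta, a, b)


class TestInformation:
    def test_peak_value_is_a_squared_over_four(self):
        assert item_information(1.3, a=2.0, b=1.3) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.2, 4), b=st.floats(-2, 2), off=st.floats(-3, 3))
    def test_maximized_at_difficulty(self, a, b, off):
        assert item_information(b, a, b) >= item_information(b + off, a, b)

    def test_vanishes_in_the_tails(self):
        assert item_information(60.0, a=2.0, b=0.0) == pytest.approx(0.0, abs=1e-12)
        assert item_information(-60.0, a=2.0, b=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_numeric_derivative_of_icc(self):
        # I(theta) = a * P'(theta) via P' = a P (1-P)
        theta, a, b, h = 0.7, 1.8, 0.2, 1e-6
        dp = (icc(theta + h, a, b) - icc(theta - h, a, b)) / (2 * h)
        assert item_information(theta, a, b) == pytest.approx(a * dp, rel=1e-6)

    def test_test_information_additive_in_items(self, bank):
        grid = LatentGrid.standard_normal()
        sub_a = ScaleDefinition("A", (1, 4, 6))
        sub_aj = ScaleDefinition("Aj", (1, 4, 6, 16))
        only_j = ScaleDefinition("j", (16,))
        lhs = expected_test_information(bank, sub_aj, grid) - expected_test_information(
            bank, sub_a, grid
        )
        assert lhs == pytest.approx(expected_test_information(bank, only_j, grid))

    def test_full_scale_dominates_subsets(self, bank, scales):
        full = expected_test_information(bank, scales["GDS30"])
        for name in ("GDS15", "GDS4", "GDS10-IRT"):
            assert full > expected_test_information(bank, scales[name])

    def test_empty_subset_rejected(self, bank):
        with pytest.raises(ValueError):
            expected_test_information(bank.subset([]), None)


class TestRanking:
    def test_reference_bank_order(self, bank):
        ranking = rank_items(bank)
        assert ranking[0] == 16
        assert set(ranking[:10].tolist()) == {1, 4, 6, 10, 11, 16, 17, 21, 22, 25}

    def test_tie_breaks(self):
        b = ItemBank(
            items=[3, 1, 2],
            a=[1.0, 1.0, 1.0],
            b=[0.0, 0.0, 0.0],
            item_auc=[0.6, 0.6, 0.9],
        )
        # higher AUC first, then ascending item index
        assert rank_items(b).tolist() == [2, 1, 3]
        b2 = ItemBank(items=[3, 1, 2], a=[1.0, 1.0, 1.0], b=[0.0, 0.0, 0.0])
        assert rank_items(b2).tolist() == [1, 2, 3]


class TestItemAuc:
    def test_perfect_item(self):
        resp = np.array([1, 1, 0, 0, 0])
        diag = np.array([1, 1, 0, 0, 0])
        assert item_auc(resp, diag) == 1.0

    def test_population_value_by_pair_enumeration(self):
        """Cases endorse at 0.8, controls at 0.2: pair counting gives
        0.8*0.8 + 0.5*(0.8*0.2 + 0.2*0.8) = 0.80 = (sens+spec)/2."""
        rng = np.random.default_rng(5)
        diag = np.repeat([1, 0], [2000, 8000])
        resp = np.where(
            diag == 1, rng.random(10000) < 0.8, rng.random(10000) < 0.2
        ).astype(int)
        cases, controls = resp[diag == 1], resp[diag == 0]
        gt = np.mean(cases[:, None] > controls[None, :])
        eq = np.mean(cases[:, None] == controls[None, :])
        brute = gt + 0.5 * eq
        assert item_auc(resp, diag) == pytest.approx(brute, abs=1e-12)
        assert brute == pytest.approx(0.80, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            item_auc(np.array([0, 1]), np.array([1, 1]))


class TestCronbach:
    def test_duplicate_columns_give_one(self):
        col = np.array([0, 1, 1, 0, 1, 0, 1, 1])
        assert cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(8)
        x = (rng.random((5000, 6)) < 0.5).astype(int)
        assert abs(cronbach_alpha(x)) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((10, 1)))

    def test_short_form_band_on_synthetic_cohorts(self, scales):
        """GDS10-IRT alpha stays in a band bracketing strong internal
        consistency under the default generator."""
        alphas = [
            cronbach_alpha(
                generate_cohort(CohortConfig(seed=s)).responses,
                scales["GDS10-IRT"],
            )
            for s in range(10)
        ]
        assert min(alphas) > 0.75 and max(alphas) < 0.90


class TestFit2PL:
    def test_two_item_recovery_large_n(self):
        bank = ItemBank([1, 2], [1.5, 1.5], [-1.0, 1.0])
        cfg = CohortConfig(
            n_subjects=50000,
            item_bank=bank,
            theta_case=(0.0, 1.0),
            theta_control=(0.0, 1.0),
            source_spec=None,
            prevalence=0.5,
            seed=101,
        )
        cohort = generate_cohort(cfg)
        res = TwoPLModel(cohort.responses, item_ids=[1, 2]).fit()
        assert res.converged
        np.testing.assert_allclose(res.item_bank.b, [-1.0, 1.0], atol=0.05)

    def test_reference_bank_recovery(self, bank):
        """Discrimination order and difficulty scale recovered at n=5000."""
        cfg = CohortConfig(
            n_subjects=5000,
            theta_case=(0.0, 1.0),
            theta_control=(0.0, 1.0),
            source_spec=None,
            prevalence=0.5,
            seed=7,
        )
        cohort = generate_cohort(cfg)
        res = TwoPLModel(cohort.responses).fit()
        est = res.item_bank
        assert np.corrcoef(est.a, bank.a)[0, 1] > 0.9
        assert np.abs(est.b - bank.b).mean() < 0.25

    def test_loglike_monotone_nondecreasing(self, dev_fit):
        diffs = np.diff(dev_fit.loglike_path)
        assert np.all(diffs >= -1e-6)

    def test_difficulty_anticorrelates_with_endorsement(self, dev_fit, halves):
        from scipy.stats import spearmanr

        dev, _ = halves
        rates = dev.responses.mean().to_numpy()
        rho = spearmanr(dev_fit.item_bank.b, rates).statistic
        assert rho < -0.8

    def test_no_information_items_near_lower_bound(self):
        """Items with no latent-trait dependence collapse toward the a_min
        bound (a residual spurious slope remains with tiny item pools)."""
        rng = np.random.default_rng(55)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = TwoPLModel((rng.random((4000, 2)) < 0.5).astype(int)).fit()
            res6 = TwoPLModel((rng.random((20000, 6)) < 0.5).astype(int)).fit()
        assert np.all(res2.item_bank.a < 0.3)
        assert np.all(res6.item_bank.a < 0.3)
        assert np.all(res6.item_bank.a >= 0.05)  # clipped at the bound

    def test_constant_item_excluded_with_warning(self):
        rng = np.random.default_rng(56)
        x = (rng.random((200, 3)) < 0.5).astype(int)
        x[:, 1] = 1
        with pytest.warns(UserWarning, match="constant"):
            res = TwoPLModel(x).fit(max_iter=50)
        assert res.item_bank.items.tolist() == [1, 3]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            TwoPLModel(np.array([[0, 2], [1, 0]]))

    def test_missing_responses_tolerated(self):
        cfg = CohortConfig(n_subjects=3000, seed=61)
        x = generate_cohort(cfg).responses.to_numpy().astype(float)
        rng = np.random.default_rng(62)
        x[rng.random(x.shape) < 0.1] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = TwoPLModel(x).fit(max_iter=200)
        assert np.isfinite(res.item_bank.a).all()

    def test_summary_mentions_convergence(self, dev_fit):
        s = dev_fit.summary()
        assert "converged: True" in s and "items: 30" in s
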