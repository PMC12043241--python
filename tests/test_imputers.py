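"""CIM, EM and MI imputers against closed-form and hand-computed oracles."""

import numpy as np
import pytest

import imputedim as im
from imputedim.core import round_and_clip

from conftest import mvn_with_missing


def _match_pct(result, original, mask):
    return 100.0 * np.mean(result.completed.values[mask] == original.values[mask])


class TestRoundAndClip:
    @pytest.mark.parametrize(
        "raw,expected",
        [(5.6, 5), (2.5, 3), (0.4, 1), (3.49, 3), (1.5, 2), (4.5, 5), (-0.7, 1)],
    )
    def test_half_away_from_zero_then_clamp(self, raw, expected):
        assert round_and_clip(np.array([raw]))[0] == expected


class TestCim:
    def _toy(self):
        # observed item means are exactly (2, 3, 4); respondent 0 has
        # item 3 missing and observed scores (3, 4)
        values = np.array(
            [
                [3, 4, np.nan],
                [1, 3, 4],
                [2, 2, 4],
                [2, 3, 4],
            ]
        )
        return im.IncompleteMatrix(values=values, mask=np.isnan(values))

    def test_hand_calculated_toy(self):
        # PM = 3.5, mean of item means over observed = 2.5, ratio = 1.4,
        # raw = 1.4 * 4 = 5.6 -> rounds to 6 -> clips to 5
        inc = self._toy()
        result = im.cim_impute(inc)
        assert result.raw[0, 2] == pytest.approx(5.6)
        assert result.completed.values[0, 2] == 5

    def test_respondent_matching_item_means_gets_item_mean(self):
        values = np.array(
            [
                [2.0, 3.0, np.nan],
                [1.0, 2.0, 4.0],
                [3.0, 4.0, 4.0],
                [2.0, 3.0, 4.0],
            ]
        )
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        result = im.cim_impute(inc)
        # row 0 sits exactly at the observed item means -> ratio 1
        assert result.raw[0, 2] == pytest.approx(4.0)

    def test_unobserved_item_raises_with_item_name(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        with pytest.raises(ValueError, match="item 2"):
            im.cim_impute(inc)

    def test_empty_respondent_falls_back_to_item_means(self):
        values = np.array(
            [
                [np.nan, np.nan, np.nan],
                [1.0, 3.0, 5.0],
                [3.0, 3.0, 3.0],
            ]
        )
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        result = im.cim_impute(inc)
        np.testing.assert_array_equal(result.completed.values[0], [2, 3, 4])


class TestEmFit:
    def test_complete_data_recovers_sample_moments_in_one_step(self, rng):
        x = rng.normal(size=(50, 4)) + [1, 2, 3, 4]
        inc = im.IncompleteMatrix(values=x, mask=np.zeros_like(x, bool))
        params = im.em_fit(inc)
        np.testing.assert_allclose(params.mu, x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            params.sigma, np.cov(x, rowvar=False, ddof=0), atol=1e-6
        )

    def test_bivariate_monotone_matches_closed_form_mle(self, rng):
        # Anderson's factored solution for x2 missing on a subset:
        # regression of x2 on x1 from the complete rows, extended by the
        # full-sample mean/variance of x1.
        n, n_cc = 500, 300
        x = rng.multivariate_normal([0, 1], [[1.0, 0.8], [0.8, 1.5]], size=n)
        mask = np.zeros((n, 2), bool)
        mask[n_cc:, 1] = True
        inc = im.IncompleteMatrix(np.where(mask, np.nan, x), mask)
        params = im.em_fit(inc, tol=1e-10)

        mu1 = x[:, 0].mean()
        s11 = x[:, 0].var()
        cc = x[:n_cc]
        beta1 = np.cov(cc.T, ddof=0)[0, 1] / cc[:, 0].var()
        beta0 = cc[:, 1].mean() - beta1 * cc[:, 0].mean()
        resid = cc[:, 1] - beta0 - beta1 * cc[:, 0]
        s22_1 = (resid**2).mean()
        mu2 = beta0 + beta1 * mu1
        s12 = beta1 * s11
        s22 = s22_1 + beta1**2 * s11

        np.testing.assert_allclose(params.mu, [mu1, mu2], atol=1e-6)
        np.testing.assert_allclose(
            params.sigma, [[s11, s12], [s12, s22]], atol=1e-5
        )

    def test_loglik_monotone_on_random_instances(self, rng):
        for _ in range(20):
            inc = mvn_with_missing(60, 4, 0.25, rng)
            params = im.em_fit(inc, max_iter=100, tol=1e-8)
            assert np.all(np.diff(params.loglik_trace) >= -1e-7)

    def test_sigma_psd_and_convergence_flag(self, small_incomplete):
        params = im.em_fit(small_incomplete)
        assert params.converged
        assert np.linalg.eigvalsh(params.sigma).min() > -1e-8

    def test_underobserved_variable_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 1.0]])
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        with pytest.raises(ValueError, match="observed at least twice"):
            im.em_fit(inc)


class TestEmImpute:
    def test_diagonal_sigma_reduces_to_item_means(self):
        mu = np.array([1.5, 3.0])
        params = im.GaussianParams(mu=mu, sigma=np.diag([1.0, 2.0]))
        values = np.array([[np.nan, 2.0], [1.0, 4.0], [2.0, 2.0]])
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        result = im.em_impute(inc, params=params)
        assert result.raw[0, 0] == pytest.approx(1.5)

    def test_bivariate_regression_prediction(self):
        # conditional mean mu2 + s21/s11 * (x1 - mu1), computed by hand
        params = im.GaussianParams(
            mu=np.array([2.0, 3.0]),
            sigma=np.array([[1.0, 0.9], [0.9, 1.0]]),
        )
        values = np.array([[4.0, np.nan], [1.0, 2.0], [2.0, 3.0]])
        inc = im.IncompleteMatrix(values=values, mask=np.isnan(values))
        result = im.em_impute(inc, params=params)
        assert result.raw[0, 1] == pytest.approx(3.0 + 0.9 * (4.0 - 2.0))
        assert result.completed.values[0, 1] == 5  # 4.8 -> round -> clip

    def test_observed_cells_untouched(self, small_complete, small_incomplete):
        result = im.em_impute(small_incomplete)
        obs = ~small_incomplete.mask
        np.testing.assert_array_equal(
            result.completed.values[obs], small_complete.values[obs]
        )


class TestMi:
    def test_m_below_two_rejected(self, small_incomplete):
        with pytest.raises(ValueError, match="m >= 2"):
            im.mi_impute(small_incomplete, m=1, seed=0)

    def test_observed_cells_untouched_and_in_range(self, small_complete):
        inc = im.apply_mcar(small_complete, 0.2, seed=5)
        result = im.mi_impute(inc, m=3, iterations=30, burn_in=10, seed=5)
        obs = ~inc.mask
        np.testing.assert_array_equal(
            result.completed.values[obs], small_complete.values[obs]
        )
        assert len(result.m_datasets) == 3
        for d in result.m_datasets:
            assert d.values.min() >= 1 and d.values.max() <= 5

    def test_between_imputation_variance_positive(self, small_complete):
        inc = im.apply_mcar(small_complete, 0.2, seed=6)
        result = im.mi_impute(inc, m=5, iterations=50, burn_in=20, seed=6)
        draws = np.array([r[inc.mask] for r in result.raw_datasets])
        assert draws.var(axis=0).mean() > 0

    def test_consensus_concentrates_at_em_conditional_mean(self):
        # for large m the posterior-mean imputation approaches the EM
        # conditional mean; tolerance 3 Monte-Carlo se of the cell means
        bank = im.sample_item_bank(4, 400, seed=31)
        complete = im.generate_responses(bank, seed=31)
        inc = im.apply_mcar(complete, 0.15, seed=31)
        em_result = im.em_impute(inc, params=im.em_fit(inc, tol=1e-8))
        mi_result = im.mi_impute(
            inc, m=40, iterations=400, burn_in=100, seed=17
        )
        draws = np.array([r[inc.mask] for r in mi_result.raw_datasets])
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        diff = np.abs(mi_result.raw[inc.mask] - em_result.raw[inc.mask])
        assert np.mean(diff <= 3 * se + 0.05) > 0.95

    def test_seeded_sampler_reproducible(self, small_complete):
        inc = im.apply_mcar(small_complete, 0.2, seed=8)
        r1 = im.mi_impute(inc, m=3, iterations=30, burn_in=10, seed=9)
        r2 = im.mi_impute(inc, m=3, iterations=30, burn_in=10, seed=9)
        np.testing.assert_array_equal(r1.completed.values, r2.completed.values)


class TestMatchOrdering:
    def test_cim_untouched_observed(self, small_complete, small_incomplete):
        result = im.cim_impute(small_incomplete)
        obs = ~small_incomplete.mask
        np.testing.assert_array_equal(
            result.completed.values[obs], small_complete.values[obs]
        )

    def test_em_match_exceeds_cim_match(self, small_complete):
        inc = im.apply_mcar(small_complete, 0.2, seed=13)
        em_m = _match_pct(im.em_impute(inc), small_complete, inc.mask)
        cim_m = _match_pct(im.cim_impute(inc), small_complete, inc.mask)
        assert em_m > cim_m
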