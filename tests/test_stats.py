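import numpy as np
import pytest
import scipy.stats as sps

from netresp.stats import (CollinearityError, DegenerateDataError,
                           benjamini_hochberg, compare_correlations,
                           compensation_screen,
                           implied_mediator_outcome_corr, mediate,
                           moderation_test, one_sample_t, pearson_ci,
                           residualize)


def _correlated_pair(rng, n, r):
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return x, y


class TestResidualize:
    def test_orthogonality(self, rng):
        y = rng.standard_normal(200)
        C = rng.standard_normal((200, 3))
        res = residualize(y, C)
        X = np.column_stack([np.ones(200), C])
        assert np.all(np.abs(X.T @ res) < 1e-8)

    def test_idempotent(self, rng):
        y = rng.standard_normal(100)
        C = rng.standard_normal((100, 2))
        once = residualize(y, C)
        twice = residualize(once, C)
        assert np.allclose(once, twice, atol=1e-10)

    def test_none_covariates_centers(self, rng):
        y = rng.standard_normal(50) + 3.0
        res = residualize(y, None)
        assert np.allclose(res, y - y.mean())

    def test_rank_deficient_raises(self, rng):
        y = rng.standard_normal(30)
        c = rng.standard_normal(30)
        with pytest.raises(CollinearityError):
            residualize(y, np.column_stack([c, 2 * c]))


class TestPearsonCI:
    def test_fisher_ci_closed_form(self, rng):
        # at n = 103, the CI half-width in z-space is exactly 1.96/10
        x, y = _correlated_pair(rng, 103, 0.5)
        res = pearson_ci(x, y)
        z = np.arctanh(res.r)
        half = 1.959963984540054 / np.sqrt(100)
        assert np.isclose(res.ci_low, np.tanh(z - half))
        assert np.isclose(res.ci_high, np.tanh(z + half))

    def test_p_matches_scipy(self, rng):
        x, y = _correlated_pair(rng, 40, 0.3)
        res = pearson_ci(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert np.isclose(res.r, ref_r)
        assert np.isclose(res.p, ref_p)

    def test_perfect_correlation_boundary(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            pearson_ci(np.ones(10), np.arange(10.0))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pearson_ci(np.arange(3.0), np.arange(3.0))


class TestCompareCorrelations:
    def test_independent_z_hand_computed(self):
        res = compare_correlations(0.6, 103, 0.3, 53)
        z_expected = (np.arctanh(0.6) - np.arctanh(0.3)) / \
            np.sqrt(1 / 100 + 1 / 50)
        assert np.isclose(res.statistic, z_expected)
        assert res.kind == "independent-z"
        assert np.isclose(res.p, 2 * sps.norm.sf(abs(z_expected)))

    def test_dependent_t_hand_computed(self):
        r1, r2, r12, n = 0.5, 0.2, 0.3, 103
        res = compare_correlations(r1, n, r2, n, r12=r12)
        detR = 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12
        rbar = 0.5 * (r1 + r2)
        denom = 2 * (n - 1) / (n - 3) * detR + rbar**2 * (1 - r12)**3
        t_expected = (r1 - r2) * np.sqrt((n - 1) * (1 + r12) / denom)
        assert np.isclose(res.statistic, t_expected)
        assert res.kind == "dependent-t"
        assert res.df == n - 3

    def test_equal_correlations_give_zero_statistic(self):
        res = compare_correlations(0.4, 50, 0.4, 80)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_dependent_requires_equal_n(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 50, 0.2, 60, r12=0.1)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 50, 0.2, 50)


class TestModeration:
    def test_planted_interaction_detected(self, rng):
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.5 * x + 0.3 * z + 0.6 * x * z + 0.3 * rng.standard_normal(n)
        res = moderation_test(y, x, z)
        assert res.interaction_coef > 0.4
        assert res.p < 1e-6
        assert res.partial_r2 > 0.1

    def test_interaction_coefficient_recovers_truth(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.25 * x * z + 0.1 * rng.standard_normal(n)
        res = moderation_test(y, x, z)
        assert np.isclose(res.interaction_coef, 0.25, atol=0.02)

    def test_rank_deficient_raises(self, rng):
        x = rng.standard_normal(40)
        with pytest.raises(CollinearityError):
            moderation_test(rng.standard_normal(40), x, x.copy())


class TestMediation:
    def test_effect_decomposition_exact(self, rng):
        n = 200
        x = rng.standard_normal(n)
        m = 0.6 * x + rng.standard_normal(n)
        y = 0.5 * m + 0.2 * x + rng.standard_normal(n)
        res = mediate(x, m, y, n_boot=50, seed=0)
        assert abs(res.acme + res.ade - res.total) < 1e-8

    def test_full_mediation(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        m = 0.8 * x + 0.1 * rng.standard_normal(n)
        y = 0.7 * m + 0.1 * rng.standard_normal(n)
        res = mediate(x, m, y, n_boot=100, seed=0)
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.05)

    def test_zero_total_effect_reports_none(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        # make y exactly orthogonal to x so the total effect is 0
        y = residualize(y, x[:, None])
        m = rng.standard_normal(n)
        m = residualize(m, np.column_stack([x, y]))
        res = mediate(x, m, y, n_boot=50, seed=0)
        assert res.proportion_mediated is None
        assert res.proportion_ci is None

    def test_bootstrap_ci_brackets_point(self, rng):
        n = 300
        x = rng.standard_normal(n)
        m = 0.6 * x + rng.standard_normal(n)
        y = 0.5 * m + 0.2 * x + rng.standard_normal(n)
        res = mediate(x, m, y, n_boot=400, seed=3)
        assert res.acme_ci[0] <= res.acme <= res.acme_ci[1]
        assert res.total_ci[0] <= res.total <= res.total_ci[1]

    def test_deterministic_under_seed(self, rng):
        n = 100
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.5 * m + rng.standard_normal(n)
        a = mediate(x, m, y, n_boot=100, seed=7)
        b = mediate(x, m, y, n_boot=100, seed=7)
        assert a == b

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            mediate(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestImpliedCorrelation:
    def test_round_trip_proportion(self):
        # plugging the implied r(m, y) back into the product-of-coefficients
        # identity must return the requested proportion exactly
        for r_xm, r_xy, prop in ((-0.72, -0.68, 0.48), (-0.42, -0.59, 0.21)):
            r_my = implied_mediator_outcome_corr(r_xm, r_xy, prop)
            b = (r_my - r_xy * r_xm) / (1 - r_xm**2)
            assert np.isclose(r_xm * b / r_xy, prop, atol=1e-12)

    def test_implied_matrix_positive_definite(self):
        for r_xm, r_xy, prop in ((-0.72, -0.68, 0.48), (-0.42, -0.59, 0.21)):
            r_my = implied_mediator_outcome_corr(r_xm, r_xy, prop)
            C = np.array([[1, r_xm, r_xy], [r_xm, 1, r_my], [r_xy, r_my, 1]])
            assert np.linalg.eigvalsh(C).min() > 0

    def test_zero_r_xm_rejected(self):
        with pytest.raises(ValueError):
            implied_mediator_outcome_corr(0.0, -0.5, 0.4)


class TestOneSampleT:
    def test_matches_scipy(self, rng):
        v = rng.standard_normal(30) + 0.4
        res = one_sample_t(v)
        ref = sps.ttest_1samp(v, 0.0)
        assert np.isclose(res.t, ref.statistic)
        assert np.isclose(res.p, ref.pvalue)

    def test_ci_brackets_mean(self, rng):
        v = rng.standard_normal(25)
        res = one_sample_t(v)
        assert res.ci_low <= res.mean <= res.ci_high


class TestCompensationScreen:
    def test_planted_positive_age_slope_flagged(self, rng):
        n = 120
        ages = rng.uniform(23, 87, n)
        older = ages >= 65
        R = rng.standard_normal((n, 3)) * 0.3 + 0.5
        # component 1 recruits with age within the older group
        R[older, 1] += 0.08 * (ages[older] - 65)
        scores = rng.standard_normal(n)
        out = compensation_screen(R, ages, scores, older)
        assert out[1]["test1_flag"]
        assert not out[0]["test1_flag"]

    def test_planted_interaction_flagged(self, rng):
        n = 200
        ages = rng.uniform(23, 87, n)
        older = ages >= 65
        R = rng.standard_normal((n, 2)) * 0.3 + 0.5
        ac = (ages - ages.mean()) / ages.std()
        scores = 0.8 * R[:, 0] * ac + 0.2 * rng.standard_normal(n)
        out = compensation_screen(R, ages, scores, older)
        assert out[0]["test2_flag"]

    def test_empty_older_group_raises(self, rng):
        R = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            compensation_screen(R, np.full(20, 30.0),
                                rng.standard_normal(20),
                                np.zeros(20, dtype=bool))


class TestBenjaminiHochberg:
    def test_against_known_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = benjamini_hochberg(p)
        # sorted p: 0.005, 0.01, 0.03, 0.04 -> adj 0.02, 0.02, 0.04, 0.04
        assert np.allclose(np.sort(adj), [0.02, 0.02, 0.04, 0.04])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=20)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
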