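import itertools

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pbsi.core import pbsi_scores
from pbsi.stats import (
    cliffs_delta,
    compare_pbsi,
    compare_samples,
    cv_equality_test,
    fdr_adjust,
    ks_normality,
    mann_whitney,
    spearman_assoc,
    tukey_inlier_mask,
)


def brute_cliffs(x, y):
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


def brute_u_distribution(pooled, nx):
    """U statistics over all distinguishable assignments of the pooled values."""
    pooled = list(pooled)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in idx]
        gt = sum(1 for a in x for b in y if a > b)
        ties = sum(1 for a in x for b in y if a == b)
        us.append(gt + 0.5 * ties)
    return np.asarray(us)


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = mann_whitney(x, x)
        assert res.U == 50.0  # n^2 / 2
        assert res.Z == 0.0
        assert res.p == 1.0

    def test_separated_samples_exact_p(self):
        # all C(6,3) = 20 rank assignments; both extremes -> p = 2/20 = 0.1
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.U == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.Z < 0  # first sample stochastically smaller

    def test_u_symmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney(x, y).U + mann_whitney(y, x).U == 12 * 9

    def test_p_swap_invariant(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=20)
        assert mann_whitney(x, y).p == pytest.approx(mann_whitney(y, x).p)

    def test_tie_corrected_sigma_matches_permutation_variance(self):
        x = [1.0, 1.0, 2.0]
        y = [1.0, 2.0, 2.0]
        us = brute_u_distribution(x + y, 3)
        # recover sigma from the package's Z at an asymmetric point
        res = mann_whitney(x, y)
        diff = res.U - 4.5  # mu = nx*ny/2
        if res.Z != 0.0:
            sigma_pkg = (diff - 0.5 * np.sign(diff)) / res.Z
            assert sigma_pkg == pytest.approx(us.std(ddof=0), rel=1e-12)
        # and the permutation-null mean matches mu
        assert us.mean() == pytest.approx(4.5)

    def test_tie_corrected_sigma_formula_against_brute_force(self):
        pooled = [1.0, 1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        nx = 3
        us = brute_u_distribution(pooled, nx)
        n = len(pooled)
        ny = n - nx
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        sigma2 = nx * ny / 12 * ((n + 1) - tie_term)
        assert sigma2 == pytest.approx(us.var(ddof=0), rel=1e-12)

    def test_large_sample_matches_scipy_normal_approx(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0.3, 1, 60)
        res = mann_whitney(x, y)
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestCliffsDelta:
    def test_same_multiset_is_zero(self):
        assert cliffs_delta([1, 2, 2, 3], [3, 2, 1, 2]) == 0.0

    def test_bounds(self):
        assert cliffs_delta([5, 6, 7], [1, 2, 3]) == 1.0
        assert cliffs_delta([1, 2, 3], [5, 6, 7]) == -1.0

    def test_matches_all_pairs_brute_force(self, rng):
        x = rng.integers(0, 10, size=13).astype(float)
        y = rng.integers(0, 10, size=17).astype(float)
        assert cliffs_delta(x, y) == brute_cliffs(x, y)

    @given(
        hnp.arrays(np.float64, st.integers(1, 8), elements=st.floats(-5, 5)),
        hnp.arrays(np.float64, st.integers(1, 8), elements=st.floats(-5, 5)),
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_and_bounds(self, x, y):
        d = cliffs_delta(x, y)
        assert d == -cliffs_delta(y, x)
        assert -1.0 <= d <= 1.0
        assert d == brute_cliffs(x, y)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=12)
        assert cliffs_delta(x, y) == cliffs_delta(np.exp(x), np.exp(y))

    def test_empty_input(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])


class TestKSNormality:
    def test_null_statistic_small(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(3, 2, 500)
            stat, p = ks_normality(x)
            assert stat < 0.1
            rejections += p < 0.001
        assert rejections <= 4

    def test_bimodal_rejected(self):
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-4, 0.5, 100), rng.normal(4, 0.5, 100)])
            _, p = ks_normality(x)
            rejections += p < 0.05
        assert rejections >= 38  # >= 95% of seeds

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0, 4.0])


class TestCVEquality:
    def test_duplicated_sample_null(self, rng):
        x = rng.normal(10, 2, 30)
        res = cv_equality_test([x, x.copy()])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 1

    def test_scale_invariance(self, rng):
        a, b = rng.normal(10, 2, 25), rng.normal(12, 1, 30)
        r1 = cv_equality_test([a, b])
        r2 = cv_equality_test([7.5 * a, 7.5 * b])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_three_group_df(self, rng):
        samples = [rng.normal(10, 2, 20) for _ in range(3)]
        assert cv_equality_test(samples).df == 2

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        n_sim, alpha = 2000, 0.05
        rejections = sum(
            cv_equality_test([rng.normal(10, 2, 50), rng.normal(10, 2, 50)]).p_value < alpha
            for _ in range(n_sim)
        )
        # binomial 99% band around 0.05
        half = 2.576 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert alpha - half <= rejections / n_sim <= alpha + half

    def test_power_cv_point1_vs_point3(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            cv_equality_test([rng.normal(10, 1.0, 50), rng.normal(10, 3.0, 50)]).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 > 0.9

    def test_non_positive_mean_errors(self, rng):
        with pytest.raises(ValueError, match="non-positive"):
            cv_equality_test([rng.normal(-5, 1, 20), rng.normal(10, 1, 20)])

    def test_single_group_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            cv_equality_test([rng.normal(10, 1, 20)])


class TestSpearmanAssoc:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = spearman_assoc(x, np.exp(x))
        assert rho == 1.0
        assert p == 0.0

    def test_agrees_with_core_kernel(self, rng):
        from pbsi.core import spearman_rho

        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = spearman_assoc(x, y)
        assert rho == spearman_rho(x, y)

    def test_type_i_error(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            spearman_assoc(rng.normal(size=100), rng.normal(size=100))[1] < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_constant_input_flagged(self):
        rho, p = spearman_assoc(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)


class TestFDR:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert fdr_adjust([0.037])[0] == 0.037

    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_adjust(p), ref, atol=1e-12)

    def test_pointwise_at_least_input(self, rng):
        p = rng.uniform(size=25)
        assert (fdr_adjust(p) >= p).all()

    def test_preserves_significance_order(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCompare:
    def _result(self, scores, cell):
        import pandas as pd

        from pbsi.core import PBSIResult

        return PBSIResult(
            cell=cell,
            scores=pd.Series(scores, index=[f"s{i}" for i in range(len(scores))]),
            n_peers=len(scores) - 1,
        )

    def test_modality_mismatch_errors(self, rng):
        a = self._result(rng.uniform(0, 1, 10), ("hc", "A", "CT"))
        b = self._result(rng.uniform(0, 1, 10), ("scz", "A", "SV"))
        with pytest.raises(ValueError, match="modalities"):
            compare_pbsi(a, b)

    def test_cross_site_requires_override(self, rng):
        a = self._result(rng.uniform(0, 1, 10), ("hc", "A", "CT"))
        b = self._result(rng.uniform(0, 1, 10), ("hc", "B", "CT"))
        with pytest.raises(ValueError, match="cross_site"):
            compare_pbsi(a, b)
        out = compare_pbsi(a, b, cross_site=True)
        assert out.contrast[0] == "hc@A"

    def test_sign_convention(self):
        low = np.linspace(0.1, 0.3, 20)
        high = np.linspace(0.6, 0.9, 20)
        comp = compare_samples(low, high, ("low", "high", "pbsi"))
        assert comp.Z < 0 and comp.cliffs_d == -1.0

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(200):
            x, y = rng.normal(size=(2, 40))
            comp = compare_samples(x, y, ("a", "b", "v"), outlier_k=None)
            rejections += comp.p_raw < 0.05
        assert rejections / 200 < 0.12

    def test_trimmed_and_untrimmed_sign_agreement(self):
        rng = np.random.default_rng(5)
        agree = 0
        for _ in range(30):
            x = rng.normal(0.0, 1, 40)
            y = rng.normal(0.5, 1, 40)
            comp = compare_samples(x, y, ("a", "b", "v"))
            agree += np.sign(comp.cliffs_d) == np.sign(comp.trimmed["cliffs_d"])
        assert agree >= 27

    def test_dispersion_contrast_power(self):
        from pbsi.cohort import CohortSpec, generate_cohort

        rejections = 0
        for seed in range(10):
            spec = CohortSpec(
                n_per_group=60, groups=("lo", "hi"), n_ct_regions=64,
                within_group_dispersion={"lo": 0.1, "hi": 1.0}, seed=seed,
            )
            cohort = generate_cohort(spec)
            values = cohort.table.profiles("CT").to_numpy()
            groups = cohort.table.data["group"].to_numpy()
            s_lo = pbsi_scores(values[groups == "lo"])
            s_hi = pbsi_scores(values[groups == "hi"])
            comp = compare_samples(s_lo, s_hi, ("lo", "hi", "pbsi_CT"))
            assert comp.cliffs_d > 0  # construction guarantees direction
            rejections += comp.p_raw < 0.05
        assert rejections >= 9


class TestTukeyMask:
    def test_no_outliers_all_true(self):
        assert tukey_inlier_mask(np.arange(10.0)).all()

    def test_extreme_point_excluded(self):
        v = np.array([1.0, 2, 3, 4, 5, 100.0])
        mask = tukey_inlier_mask(v)
        assert not mask[-1] and mask[:-1].all()
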