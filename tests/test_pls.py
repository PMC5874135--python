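"""Grouped PLS core: normalization, SVD, permutation and bootstrap contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import seedpls
from seedpls.errors import AgeOutOfRangeError, DegenerateVarianceError
from seedpls.pls import (
    AgeGroupScheme,
    _group_indices,
    assign_groups,
    bootstrap_saliences,
    brain_scores,
    covariance_stack,
    decompose,
    group_correlations,
    group_normalize,
    permutation_test,
    select_lvs,
    threshold_pattern,
)


def _toy(n_per_group=4, n_groups=3, n_vox=50, seed=0, signal=0.0):
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    groups = np.repeat(np.arange(n_groups), n_per_group)
    X = rng.normal(size=(n, n_vox))
    Y = rng.normal(size=n) + signal * X[:, 0]
    return X, Y, groups


class TestAssignGroups:
    @pytest.mark.parametrize(
        "age, expected",
        [(6, 0), (15, 0), (15.9, 0), (16, 1), (35, 2), (36, 3), (59.5, 3), (94.9, 5)],
    )
    def test_bin_membership(self, age, expected):
        assert assign_groups([age])[0] == expected

    @pytest.mark.parametrize("age", [5, 5.9, 95, -1])
    def test_out_of_range(self, age):
        with pytest.raises(AgeOutOfRangeError):
            assign_groups([age])

    def test_scheme_must_be_contiguous(self):
        with pytest.raises(ValueError):
            AgeGroupScheme(bins=((6, 15), (17, 25)))


class TestGroupNormalize:
    @given(seed=st.integers(0, 1000))
    def test_blocks_centered_unit_norm(self, seed):
        X, Y, groups = _toy(seed=seed)
        Xn, Yn = group_normalize(X, Y, groups)
        for idx in _group_indices(groups):
            np.testing.assert_allclose(Xn[idx].mean(axis=0), 0, atol=1e-12)
            np.testing.assert_allclose(
                np.linalg.norm(Xn[idx], axis=0), 1, atol=1e-12
            )
            assert abs(Yn[idx].sum()) < 1e-12
            assert np.linalg.norm(Yn[idx]) == pytest.approx(1.0, abs=1e-12)

    def test_self_correlation_is_one(self):
        X, _, groups = _toy()
        Y = X[:, 7].copy()
        Xn, Yn = group_normalize(X, Y, groups)
        Z = covariance_stack(Xn, Yn, groups)
        np.testing.assert_allclose(Z[:, 7], 1.0, atol=1e-12)

    def test_orthogonal_voxel_gives_zero(self):
        X, Y, groups = _toy()
        # make voxel 3 orthogonal to Y after centering, within each group
        for idx in _group_indices(groups):
            yg = Y[idx] - Y[idx].mean()
            xg = X[idx, 3] - X[idx, 3].mean()
            X[idx, 3] = xg - (xg @ yg) / (yg @ yg) * yg
        Xn, Yn = group_normalize(X, Y, groups)
        Z = covariance_stack(Xn, Yn, groups)
        np.testing.assert_allclose(Z[:, 3], 0.0, atol=1e-12)

    def test_zero_variance_voxel_named(self):
        X, Y, groups = _toy()
        X[groups == 1, 5] = 2.0
        with pytest.raises(DegenerateVarianceError) as err:
            group_normalize(X, Y, groups)
        assert err.value.group == 1
        assert err.value.column == 5

    def test_small_group_rejected(self):
        X, Y, _ = _toy()
        groups = np.array([0, 0, 1, 1] + [2] * 8)
        with pytest.raises(DegenerateVarianceError):
            group_normalize(X, Y, groups)


class TestCovarianceStack:
    def test_matches_bruteforce_pearson(self):
        X, Y, groups = _toy(n_per_group=4, n_groups=3, n_vox=50, seed=3)
        Xn, Yn = group_normalize(X, Y, groups)
        Z = covariance_stack(Xn, Yn, groups)
        for g, idx in enumerate(_group_indices(groups)):
            for v in range(X.shape[1]):
                r = stats.pearsonr(Y[idx], X[idx, v]).statistic
                assert Z[g, v] == pytest.approx(r, abs=1e-10)

    def test_entries_bounded_by_one(self):
        X, Y, groups = _toy(seed=9)
        Xn, Yn = group_normalize(X, Y, groups)
        assert np.max(np.abs(covariance_stack(Xn, Yn, groups))) <= 1 + 1e-12

    def test_mean_magnitude_shrinks_with_group_size(self):
        mags = []
        for n in (5, 50):
            acc = []
            for seed in range(5):
                X, Y, groups = _toy(n_per_group=n, seed=seed)
                Xn, Yn = group_normalize(X, Y, groups)
                acc.append(np.abs(covariance_stack(Xn, Yn, groups)).mean())
            mags.append(np.mean(acc))
        assert mags[1] < mags[0] / 2


class TestDecompose:
    def test_reconstruction_and_conservation(self):
        X, Y, groups = _toy(seed=4)
        Xn, Yn = group_normalize(X, Y, groups)
        Z = covariance_stack(Xn, Yn, groups)
        lv = decompose(Z)
        rec = lv.u @ np.diag(lv.singular_values) @ lv.v.T
        assert np.linalg.norm(rec - Z) / np.linalg.norm(Z) < 1e-8
        assert lv.cov_explained.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(lv.u.T @ lv.u, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(lv.v.T @ lv.v, np.eye(3), atol=1e-8)
        assert np.all(np.diff(lv.singular_values) <= 1e-12)

    def test_rank_one_stack(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=40)
        v /= np.linalg.norm(v)
        lv = decompose(6.0 * np.outer(u, v))
        assert lv.cov_explained[0] == pytest.approx(100.0)
        assert np.all(lv.singular_values[1:] < 1e-10)

    def test_sign_convention(self):
        X, Y, groups = _toy(seed=6)
        Xn, Yn = group_normalize(X, Y, groups)
        lv = decompose(covariance_stack(Xn, Yn, groups))
        for j in range(lv.n_lvs):
            assert lv.u[np.argmax(np.abs(lv.u[:, j])), j] > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.array([[1.0, np.nan]]))


class TestPermutationTest:
    def test_perfect_signal_attains_floor(self):
        """Y duplicated from a voxel gives the smallest attainable p."""
        X, _, groups = _toy(n_per_group=10, n_vox=30, seed=7)
        Y = X[:, 0] + 0.01 * np.random.default_rng(8).normal(size=X.shape[0])
        p, _ = permutation_test(X, Y, groups, n_perm=200,
                                rng=np.random.default_rng(1))
        assert p[0] == pytest.approx(1 / 201)

    def test_p_values_in_unit_interval(self):
        X, Y, groups = _toy(seed=10)
        p, n_redrawn = permutation_test(X, Y, groups, n_perm=150,
                                        rng=np.random.default_rng(2))
        assert np.all((p > 0) & (p <= 1))
        assert n_redrawn == 0

    def test_zero_permutations_rejected(self):
        X, Y, groups = _toy()
        with pytest.raises(ValueError):
            permutation_test(X, Y, groups, n_perm=0)

    def test_voxel_relabeling_invariance(self):
        """Permuting voxel order changes no scalar output and permutes V."""
        X, Y, groups = _toy(n_per_group=6, n_vox=40, seed=11, signal=1.0)
        perm = np.random.default_rng(12).permutation(X.shape[1])
        p1, _ = permutation_test(X, Y, groups, n_perm=100,
                                 rng=np.random.default_rng(3))
        p2, _ = permutation_test(X[:, perm], Y, groups, n_perm=100,
                                 rng=np.random.default_rng(3))
        np.testing.assert_array_equal(p1, p2)
        Xn, Yn = group_normalize(X, Y, groups)
        lv1 = decompose(covariance_stack(Xn, Yn, groups))
        Xn2, Yn2 = group_normalize(X[:, perm], Y, groups)
        lv2 = decompose(covariance_stack(Xn2, Yn2, groups))
        np.testing.assert_allclose(lv1.singular_values, lv2.singular_values, atol=1e-10)
        np.testing.assert_allclose(lv2.v, lv1.v[perm], atol=1e-8)


class TestSelectLvs:
    @pytest.mark.parametrize(
        "p, cov, expected",
        [
            (0.0002, 61.57, True),   # dominant significant pattern
            (0.0002, 4.9, False),    # significant but under the 5% floor
            (0.01, 50.0, False),     # large but not significant
            (0.0009, 5.0, True),     # boundary: >= 5% passes
            (0.001, 50.0, False),    # boundary: p must be strictly below
        ],
    )
    def test_joint_rule(self, p, cov, expected):
        assert select_lvs([p], [cov])[0] == expected


class TestThresholdPattern:
    def test_95_percent_cutoff(self):
        kept = threshold_pattern(np.array([2.0, 1.9, -2.0, 0.0]), 0.95)
        np.testing.assert_array_equal(kept, [True, False, True, False])

    def test_99_percent_cutoff_matches_normal_quantile(self):
        cutoff = stats.norm.ppf(0.995)  # 2.5758...
        kept = threshold_pattern(np.array([cutoff - 1e-3, cutoff + 1e-3]), 0.99)
        np.testing.assert_array_equal(kept, [False, True])

    def test_infinite_bsr_retained(self):
        assert threshold_pattern(np.array([np.inf]), 0.95)[0]

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5])
    def test_invalid_level(self, level):
        with pytest.raises(ValueError):
            threshold_pattern(np.zeros(3), level)


class TestBrainScores:
    def test_duplicated_pattern_projection(self):
        v = np.random.default_rng(13).normal(size=20)
        scales = np.array([1.0, 2.0, -0.5])
        X = np.outer(scales, v)
        L = brain_scores(X, v[:, None])
        np.testing.assert_allclose(L[:, 0], scales * (v @ v), atol=1e-12)

    def test_linearity(self):
        X, Y, groups = _toy(seed=14)
        Xn, Yn = group_normalize(X, Y, groups)
        lv = decompose(covariance_stack(Xn, Yn, groups))
        L = brain_scores(X, lv.v)
        X2 = X.copy()
        X2[4] *= 2
        np.testing.assert_allclose(brain_scores(X2, lv.v)[4], 2 * L[4], atol=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            brain_scores(np.zeros((3, 5)), np.zeros((4, 2)))


class TestBootstrap:
    def test_bsr_separates_planted_support(self):
        """On a strong planted pattern, support voxels clear |BSR|>=1.96 and
        off-support voxels mostly do not."""
        rng = np.random.default_rng(15)
        n_per, n_vox = 20, 60
        groups = np.repeat(np.arange(3), n_per)
        n = groups.size
        e = rng.normal(size=n)
        v_true = np.zeros(n_vox)
        v_true[:10] = 1.0 / np.sqrt(10)
        X = np.outer(e, v_true) * 5 + rng.normal(size=(n, n_vox)) * 0.2
        Y = e + 0.05 * rng.normal(size=n)
        boot = bootstrap_saliences(X, Y, groups, n_boot=200,
                                   rng=np.random.default_rng(4))
        kept = threshold_pattern(boot.bsr[:, 0], 0.95)
        assert kept[:10].all()
        assert kept[10:].mean() < 0.3
        assert boot.n_zero_se == 0

    def test_single_resample_gives_zero_se_sentinels(self):
        X, Y, groups = _toy(n_per_group=5, n_vox=10, seed=16)
        boot = bootstrap_saliences(X, Y, groups, n_boot=1,
                                   rng=np.random.default_rng(5))
        assert boot.n_zero_se == boot.bsr.size
        assert np.all(np.isinf(boot.bsr) | (boot.bsr == 0.0))

    def test_group_correlation_ci_orders(self):
        X, Y, groups = _toy(n_per_group=8, seed=17, signal=2.0)
        boot = bootstrap_saliences(X, Y, groups, n_boot=100,
                                   rng=np.random.default_rng(6))
        assert np.all(boot.r_ci_low <= boot.r_ci_high + 1e-12)
        assert np.all(np.abs(boot.r_obs) <= 1.0)


class TestGroupCorrelations:
    def test_reliability_rule(self):
        L = np.random.default_rng(18).normal(size=(12, 2))
        Y = np.random.default_rng(19).normal(size=12)
        groups = np.repeat([0, 1], 6)
        resamples = np.zeros((50, 2, 2))
        resamples[:, 0, 0] = np.linspace(-0.10, 0.20, 50)   # spans zero
        resamples[:, 0, 1] = np.linspace(0.30, 0.60, 50)    # excludes zero
        resamples[:, 1, :] = 0.5
        gc = group_correlations(L, Y, groups, r_resamples=resamples)
        assert not gc.reliable[0, 0]
        assert gc.reliable[0, 1]

    def test_degenerate_resamples_collapse_ci(self):
        L = np.random.default_rng(20).normal(size=(12, 1))
        Y = np.random.default_rng(21).normal(size=12)
        groups = np.repeat([0, 1], 6)
        resamples = np.ones((40, 2, 1))
        gc = group_correlations(L, Y, groups, r_resamples=resamples)
        np.testing.assert_allclose(gc.ci_low, 1.0)
        np.testing.assert_allclose(gc.ci_high, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_correlations(np.zeros((4, 1)), np.zeros(4), [0, 0, 1, 1])
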