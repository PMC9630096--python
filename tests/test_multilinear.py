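"""Multilinear fits, spin significance, dominance analysis and distance CV."""

from itertools import combinations
from math import ceil

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemoarch as ca
from chemoarch.multilinear import (
    DominanceAnalysis,
    _all_subset_r2,
    spin_significance_batch,
)
from chemoarch.synthgen import sample_sa_map


def oracle_dominance(X, y):
    """Naive dominance: refit every subset independently with lstsq."""
    n, p = X.shape

    def r2(subset):
        Xd = np.column_stack([np.ones(n), X[:, list(subset)]])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

    total = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        level_means = []
        for k in range(p):
            incs = [
                r2(s + (i,)) - r2(s) for s in combinations(others, k)
            ]
            level_means.append(np.mean(incs))
        total[i] = np.mean(level_means)
    return total


class TestFitMultilinear:
    def test_target_equal_to_one_column_is_perfect(self, atlas60):
        atlas, _ = atlas60
        res = ca.fit_multilinear(atlas.densities, atlas.densities[:, 3])
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_null_target_r2_inflation_vs_adjustment(self, atlas100):
        """Independent noise: raw R2 concentrates near p/(n-1), adjusted near 0."""
        atlas, _ = atlas100
        rng = np.random.default_rng(0)
        r2s, r2as = [], []
        for _ in range(100):
            y = rng.standard_normal(atlas.n_regions)
            res = ca.fit_multilinear(atlas.densities, y)
            r2s.append(res.r2)
            r2as.append(res.r2_adj)
        assert np.mean(r2s) == pytest.approx(19 / 99, abs=0.03)
        assert abs(np.mean(r2as)) < 0.04

    def test_coefficients_match_normal_equations(self, rng):
        X = rng.random((5, 2))
        y = rng.random(5)
        res = ca.fit_multilinear(X, y)
        Xd = np.column_stack([np.ones(5), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(res.coefficients, beta[1:], atol=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)

    def test_rank_deficient_design_reports_columns(self, rng):
        X = rng.random((20, 3))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ca.fit_multilinear(X, rng.random(20))

    def test_too_few_regions_rejected(self, rng):
        with pytest.raises(ValueError):
            ca.fit_multilinear(rng.random((5, 5)), rng.random(5))


class TestSpinSignificance:
    def test_planted_target_significant(self, geometry100, spins100):
        atlas, _ = ca.generate_receptor_atlas(geometry100, 19, 19, 2.0, seed=50)
        maps, _ = ca.generate_target_maps(atlas, [0, 4, 9], snr=10, seed=51)
        p = ca.spin_model_significance(atlas.densities, maps[:, 0], spins100)
        assert p <= 0.01

    def test_sa_null_target_not_systematically_significant(
        self, geometry100, atlas100
    ):
        atlas, _ = atlas100
        rng = np.random.default_rng(60)
        ps = []
        for s in range(30):
            y = sample_sa_map(geometry100, 20.0, 1.0, rng)
            spins = ca.build_spin_ensemble(geometry100, 200, seed=600 + s)
            ps.append(ca.spin_model_significance(atlas.densities, y, spins))
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform, not piled at 0

    def test_invariant_to_affine_rescaling_of_target(self, atlas60, spins60):
        atlas, _ = atlas60
        rng = np.random.default_rng(1)
        y = rng.standard_normal(atlas.n_regions)
        p1 = ca.spin_model_significance(atlas.densities, y, spins60)
        p2 = ca.spin_model_significance(atlas.densities, 5.0 * y - 3.0, spins60)
        assert p1 == p2

    def test_batch_fdr_shapes(self, atlas60, spins60, geometry):
        atlas, _ = atlas60
        maps, _ = ca.generate_target_maps(atlas, [0, 1], snr=5, n_maps=4, seed=2)
        ps, sig, p_fdr = spin_significance_batch(atlas.densities, maps, spins60)
        assert ps.shape == sig.shape == p_fdr.shape == (4,)


class TestDominance:
    def test_orthogonal_predictors_exact_attribution(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((40, 2))
        A -= A.mean(axis=0)  # center first so QR columns stay zero-mean
        q, _ = np.linalg.qr(A)
        X = q  # orthonormal, zero-mean columns
        y = X[:, 0].copy()
        res = ca.dominance(X, y)
        assert res.total_dominance[0] == pytest.approx(1.0, abs=1e-10)
        assert res.total_dominance[1] == pytest.approx(0.0, abs=1e-10)
        assert res.percent[0] == pytest.approx(100.0, abs=1e-6)

    def test_sum_identity_and_oracle_agreement(self, rng):
        for _ in range(5):
            X = rng.standard_normal((60, 5))
            y = X @ rng.standard_normal(5) + rng.standard_normal(60)
            res = ca.dominance(X, y)
            full = ca.fit_multilinear(X, y)
            assert res.total_dominance.sum() == pytest.approx(full.r2, abs=1e-10)
            assert np.allclose(res.total_dominance, oracle_dominance(X, y), atol=1e-10)
            assert res.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_predictor_splits_its_share(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, 0.5, 0.0]) + 0.3 * rng.standard_normal(50)
        base = ca.dominance(X, y)
        Xdup = np.column_stack([X, X[:, 0] + 1e-6 * rng.standard_normal(50)])
        dup = ca.dominance(Xdup, y)
        combined = dup.total_dominance[0] + dup.total_dominance[3]
        assert combined == pytest.approx(base.total_dominance[0], rel=0.05)

    def test_guard_on_predictor_count(self, rng):
        X = rng.standard_normal((40, 7))
        with pytest.raises(ValueError, match="guard"):
            ca.dominance(X, rng.standard_normal(40), max_predictors=6)

    def test_class_aggregation(self, rng):
        X = rng.standard_normal((40, 4))
        y = X @ rng.standard_normal(4)
        res = ca.dominance(X, y, classes={"a": [0, 1], "b": [2, 3]})
        expected = np.mean(res.percent[[0, 1]])
        assert res.class_aggregates["a"] == pytest.approx(expected)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_sum_identity_property(self, seed):
        r = np.random.default_rng(seed)
        X = r.standard_normal((30, 4))
        y = r.standard_normal(30)
        res = ca.dominance(X, y)
        assert res.total_dominance.sum() == pytest.approx(res.r2_full, abs=1e-8)

    def test_subset_r2_table_matches_per_subset_refits(self, rng):
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        table = _all_subset_r2(X, y)
        for k in range(1, 5):
            for s in combinations(range(4), k):
                Xd = np.column_stack([np.ones(25), X[:, list(s)]])
                beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
                r2 = 1 - ((y - Xd @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
                assert table[sum(1 << i for i in s)] == pytest.approx(r2, abs=1e-10)

    def test_estimator_interface(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        est = DominanceAnalysis(max_predictors=10)
        assert est.get_params()["max_predictors"] == 10
        est.fit(X, y)
        assert est.total_dominance_.shape == (3,)


class TestDistanceCV:
    def test_fold_structure(self, geometry100, atlas100):
        atlas, _ = atlas100
        maps, _ = ca.generate_target_maps(atlas, [0], snr=5, seed=3)
        cv = ca.distance_cv(atlas.densities, maps[:, 0], geometry100)
        assert len(cv.test_r) == 100  # one fold per source region
        n_train = ceil(0.75 * 100)
        assert n_train == 75

    def test_folds_partition_regions(self, geometry):
        from chemoarch.multilinear import _cv_folds

        for tr, te in _cv_folds(geometry, 0.75):
            assert len(tr) + len(te) == geometry.n_regions
            assert len(np.union1d(tr, te)) == geometry.n_regions

    def test_train_set_contains_source_and_nearest(self, geometry):
        from chemoarch.multilinear import _cv_folds

        folds = list(_cv_folds(geometry, 0.75))
        for source, (tr, te) in enumerate(folds):
            assert source in tr
            assert geometry.distance[source, tr].max() <= geometry.distance[
                source, te
            ].min() + 1e-12

    def test_exact_linear_target_predicts_perfectly(self, atlas100, geometry100):
        atlas, _ = atlas100
        y = atlas.densities @ np.arange(1.0, 20.0)
        cv = ca.distance_cv(atlas.densities, y, geometry100)
        assert np.allclose(cv.test_r, 1.0, atol=1e-8)

    def test_sa_noise_target_mean_test_r_near_zero(self, geometry100, atlas100):
        atlas, _ = atlas100
        rng = np.random.default_rng(8)
        means = []
        for _ in range(20):
            y = sample_sa_map(geometry100, 20.0, 1.0, rng)
            means.append(ca.distance_cv(atlas.densities, y, geometry100).mean_test_r)
        assert abs(np.mean(means)) < 0.1

    def test_null_pvalue_for_planted_target(self, geometry100, spins100):
        atlas, _ = ca.generate_receptor_atlas(geometry100, 19, 19, 2.0, seed=52)
        maps, _ = ca.generate_target_maps(atlas, [0, 4, 9], snr=10, seed=53)
        cv = ca.distance_cv(atlas.densities, maps[:, 0], geometry100, spins=spins100)
        assert cv.p_null <= 0.01
        assert cv.mean_test_r > 0.5

    def test_tiny_test_set_rejected(self, atlas60, geometry):
        atlas, _ = atlas60
        with pytest.raises(ValueError):
            ca.distance_cv(atlas.densities, atlas.densities[:, 0], geometry,
                           train_frac=0.99)
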