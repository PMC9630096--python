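"""Atlas assembly, receptor similarity, distance decay, gradient, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chemoarch as ca
from chemoarch.atlas import age_residuals, zscore


class TestCombineTracerMaps:
    def test_identical_maps_idempotent(self, rng):
        m = rng.random(20)
        out = ca.combine_tracer_maps([m, m.copy()], [3.0, 7.0])
        assert np.allclose(out, zscore(m))

    def test_perfect_anticorrelation_hits_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ca.combine_tracer_maps(
                [np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])], [1.0, 1.0]
            )

    def test_weighted_average_arithmetic(self):
        """3-region toy: weights 1:3 on the z-scored inputs, then re-z-score."""
        m1 = np.array([5.0, 1.0, 3.0])
        m2 = np.array([10.0, 30.0, 50.0])
        z1, z2 = zscore(m1), zscore(m2)
        expected = zscore((1 * z1 + 3 * z2) / 4)
        with pytest.warns(RuntimeWarning):  # deliberately weakly correlated maps
            out = ca.combine_tracer_maps([m1, m2], [1.0, 3.0])
        assert np.allclose(out, expected, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ca.combine_tracer_maps([np.ones(3), np.ones(4)], [1, 1])

    def test_low_correlation_warns(self, rng):
        a, b = rng.random(30), rng.random(30)
        with pytest.warns(RuntimeWarning):
            ca.combine_tracer_maps([a, b], [1.0, 1.0])


class TestAssembleAtlas:
    def test_reference_shape(self, rng):
        tables = {f"r{j}": rng.random(100) for j in range(19)}
        atlas = ca.assemble_atlas(tables)
        assert atlas.densities.shape == (100, 19)

    def test_columns_standardized(self, rng):
        atlas = ca.assemble_atlas({f"r{j}": rng.random(30) for j in range(5)})
        assert np.allclose(atlas.densities.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(atlas.densities.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_constant_column_rejected(self, rng):
        tables = {"a": rng.random(10), "b": np.full(10, 2.0)}
        with pytest.raises(ValueError, match="b"):
            ca.assemble_atlas(tables)

    def test_missing_value_names_location(self, rng):
        df = pd.DataFrame(rng.random((6, 3)), columns=list("abc"),
                          index=[f"reg{i}" for i in range(6)])
        df.iloc[2, 1] = np.nan
        with pytest.raises(ValueError, match="reg2"):
            ca.assemble_atlas(df)


class TestReceptorSimilarity:
    def test_duplicate_rows_correlate_perfectly(self, rng):
        dens = zscore(rng.random((10, 5)))
        dens[3] = dens[0]
        atlas = ca.ReceptorAtlas(zscore(dens), [f"r{j}" for j in range(5)],
                                 [f"g{i}" for i in range(10)])
        # duplicate fingerprints up to the column re-z-score (affine per column)
        sim = ca.receptor_similarity(atlas)
        assert sim[0, 3] == pytest.approx(1.0, abs=1e-9)

    def test_negated_fingerprint_gives_minus_one(self):
        # zero-mean columns so column z-scoring preserves the row negation
        base = np.array([[1.0, -2.0, 0.5], [-1.0, 2.0, -0.5], [0.3, 0.1, 2.0],
                         [-0.3, -0.1, -2.0]])
        atlas = ca.ReceptorAtlas(zscore(base), list("abc"), list("wxyz"))
        sim = ca.receptor_similarity(atlas)
        assert sim[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_symmetric_unit_diagonal_bounded(self, atlas100):
        sim = ca.receptor_similarity(atlas100[0])
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)
        assert sim.min() >= -1 and sim.max() <= 1

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_region_permutation_equivariance(self, seed):
        """similarity(P X) == P similarity(X) P^T for any region permutation."""
        r = np.random.default_rng(seed)
        dens = zscore(r.standard_normal((12, 5)))
        atlas = ca.ReceptorAtlas(dens, [f"r{j}" for j in range(5)],
                                 [f"g{i}" for i in range(12)])
        perm = r.permutation(12)
        permuted = ca.ReceptorAtlas(zscore(dens[perm]), list(atlas.receptor_names),
                                    [atlas.region_ids[i] for i in perm])
        sim = ca.receptor_similarity(atlas)
        sim_p = ca.receptor_similarity(permuted)
        assert np.allclose(sim_p, sim[np.ix_(perm, perm)], atol=1e-8)


class TestDistanceDecay:
    def test_noiseless_self_consistency(self, geometry):
        sim = 0.8 * np.exp(-geometry.distance / 20.0)
        fit = ca.fit_distance_decay(sim, geometry)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)
        assert fit.rate == pytest.approx(0.05, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_constant_similarity_degenerates_to_flat_fit(self, geometry):
        sim = np.full_like(geometry.distance, 0.4)
        fit = ca.fit_distance_decay(sim, geometry)
        assert fit.rate >= 0
        d = geometry.distance[np.triu_indices(geometry.n_regions, 1)].mean()
        assert fit.amplitude * np.exp(-fit.rate * d) + fit.offset == pytest.approx(
            0.4, abs=1e-6
        )

    def test_noisy_recovery_within_ten_percent(self, geometry):
        rates = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            noise = r.normal(scale=0.05, size=geometry.distance.shape)
            sim = 0.8 * np.exp(-geometry.distance / 20.0) + 0.5 * (noise + noise.T)
            rates.append(ca.fit_distance_decay(sim, geometry).rate)
        assert np.mean(rates) == pytest.approx(0.05, rel=0.10)


class TestPrincipalGradient:
    def test_rank_one_atlas(self, geometry):
        atlas, truth = ca.generate_receptor_atlas(geometry, 6, 1, 0.0, seed=3)
        pc1, varexp = ca.principal_gradient(atlas)
        assert varexp[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(np.corrcoef(pc1, truth.latent_maps[0])[0, 1]) == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one_and_decrease(self, atlas100):
        _, varexp = ca.principal_gradient(atlas100[0])
        assert varexp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(varexp) <= 1e-12)

    def test_scores_zero_mean_and_sign_convention(self, atlas100):
        atlas, _ = atlas100
        pc1, _ = ca.principal_gradient(atlas)
        assert pc1.mean() == pytest.approx(0.0, abs=1e-9)
        # loadings: correlation of each receptor with PC1; their sum is positive
        loadings = [np.corrcoef(atlas.densities[:, j], pc1)[0, 1]
                    for j in range(atlas.n_receptors)]
        assert np.sum(loadings) > 0


class TestClassAnova:
    def test_identical_groups_give_zero_f(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labs = np.array(["a", "a", "a", "b", "b", "b"])
        f, p = ca.class_anova(vals, labs)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_class_variance_overflows(self):
        f, p = ca.class_anova(np.array([0.0, 0, 0, 1, 1, 1]),
                              np.array(["a", "a", "a", "b", "b", "b"]))
        assert np.isinf(f) and p == 0.0

    def test_matches_hand_computed_sums_of_squares(self):
        # 4-class toy table, F from explicit SS_between / SS_within
        vals = np.array([2.0, 4.0, 3.0, 5.0, 8.0, 6.0, 1.0, 2.0, 9.0, 7.0, 8.0, 6.0])
        labs = np.repeat(["a", "b", "c", "d"], 3)
        grand = vals.mean()
        ss_b = sum(3 * (vals[labs == g].mean() - grand) ** 2 for g in "abcd")
        ss_w = sum(((vals[labs == g] - vals[labs == g].mean()) ** 2).sum() for g in "abcd")
        expected = (ss_b / 3) / (ss_w / 8)
        f, _ = ca.class_anova(vals, labs)
        assert f == pytest.approx(expected, rel=1e-12)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            ca.class_anova(np.arange(5.0), np.array(["a", "a", "a", "a", "b"]))


def _atlas_with_ages(rng, n=40, p=10, slope=0.0):
    ages = np.linspace(25, 65, p)
    base = rng.standard_normal((n, p))
    dens = base + slope * np.outer(rng.standard_normal(n), ages)
    meta = pd.DataFrame({"mean_age": ages}, index=[f"r{j}" for j in range(p)])
    return ca.ReceptorAtlas(zscore(dens), [f"r{j}" for j in range(p)],
                            [f"g{i}" for i in range(n)], meta)


class TestRegressAge:
    def test_age_independent_atlas_nearly_unchanged(self, rng):
        # OLS removes a 2-dof in-sample projection per region, so with p
        # receptors the residual keeps ~ (p-2)/p of each fingerprint's
        # variance even when there is no true age effect
        atlas = _atlas_with_ages(rng, p=19, slope=0.0)
        out = ca.regress_age(atlas)
        rs = [np.corrcoef(out.densities[i], atlas.densities[i])[0, 1]
              for i in range(atlas.n_regions)]
        assert np.mean(rs) > 0.9
        assert min(rs) > 0.75

    def test_residuals_orthogonal_to_age(self, rng):
        atlas = _atlas_with_ages(rng, slope=0.5)
        resid = age_residuals(atlas)
        ages = atlas.meta["mean_age"].to_numpy()
        ages_c = ages - ages.mean()
        for i in range(atlas.n_regions):
            rc = resid[i] - resid[i].mean()
            assert abs(rc @ ages_c) / (np.linalg.norm(rc) * np.linalg.norm(ages_c)) < 1e-10

    def test_exactly_linear_densities_residualize_to_zero(self, rng):
        ages = np.linspace(20, 70, 8)
        region_effect = rng.standard_normal(15)
        dens = np.outer(region_effect, ages) + 1.0
        atlas = ca.ReceptorAtlas(zscore(dens), [f"r{j}" for j in range(8)],
                                 [f"g{i}" for i in range(15)],
                                 pd.DataFrame({"mean_age": ages},
                                              index=[f"r{j}" for j in range(8)]))
        assert np.allclose(age_residuals(atlas), 0, atol=1e-10)

    def test_constant_age_rejected(self, rng):
        ages = np.full(6, 40.0)
        atlas = ca.ReceptorAtlas(zscore(rng.standard_normal((12, 6))),
                                 [f"r{j}" for j in range(6)],
                                 [f"g{i}" for i in range(12)],
                                 pd.DataFrame({"mean_age": ages},
                                              index=[f"r{j}" for j in range(6)]))
        with pytest.raises(ValueError):
            ca.regress_age(atlas)


class TestLooRobustness:
    def test_output_length_and_high_stability(self, geometry100):
        atlas, _ = ca.generate_receptor_atlas(geometry100, 19, 1, 0.3, seed=8)
        out = ca.loo_similarity_robustness(atlas)
        assert out.shape == (19,)
        assert np.all(out > 0.9)

    def test_too_few_receptors_rejected(self, rng):
        atlas = ca.assemble_atlas({f"r{j}": rng.random(10) for j in range(3)})
        with pytest.raises(ValueError):
            ca.loo_similarity_robustness(atlas)
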