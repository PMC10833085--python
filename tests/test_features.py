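import numpy as np
import pytest
from scipy.linalg import subspace_angles

from scmtl.features import (
    FAConvergenceError,
    FeatureConfig,
    FeatureError,
    combat_correct,
    fit_combat,
    fit_fa,
    fit_feature_transform,
    fit_tsvd,
    normalize_log,
    select_hvgs,
)


class TestNormalizeLog:
    def test_cell_at_target_total_is_log1p_identity(self):
        row = np.array([[4000.0, 6000.0]])
        np.testing.assert_allclose(normalize_log(row, 1e4), np.log1p(row))

    def test_zeros_stay_zero(self):
        out = normalize_log(np.array([[0, 5], [3, 0]]), 1e4)
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0

    def test_row_totals_conserved(self, rng):
        x = rng.integers(0, 20, size=(50, 20)).astype(float)
        x[:, 0] += 1  # no all-zero cells
        out = normalize_log(x, 1e4)
        np.testing.assert_allclose(np.expm1(out).sum(axis=1), 1e4, atol=1e-8)

    def test_all_zero_cell_named(self):
        with pytest.raises(FeatureError, match="cell 1"):
            normalize_log(np.array([[1, 2], [0, 0]]))


class TestSelectHVGs:
    def test_constant_gene_never_selected(self, rng):
        x = rng.normal(2, 1, size=(60, 10)).clip(0)
        x[:, 3] = 1.5  # constant
        idx = select_hvgs(x, 9)
        assert 3 not in idx

    def test_all_genes_when_n_equals_g(self, rng):
        x = rng.random((30, 12))
        np.testing.assert_array_equal(select_hvgs(x, 12), np.arange(12))

    def test_planted_high_variance_recovered(self):
        # equal means, 10x the variance for 10 planted genes; single bin so
        # the ranking is on the dispersion statistic alone
        rng = np.random.default_rng(1)
        n, g = 200, 40
        x = rng.gamma(shape=10.0, scale=0.3, size=(n, g))
        planted = rng.choice(g, size=10, replace=False)
        x[:, planted] = rng.gamma(shape=1.0, scale=3.0, size=(n, 10))
        idx = select_hvgs(np.log1p(x), 10, n_bins=1)
        assert set(map(int, idx)) == set(map(int, planted))

    def test_too_many_requested(self, rng):
        with pytest.raises(FeatureError):
            select_hvgs(rng.random((10, 5)), 6)


class TestCombat:
    def test_single_batch_identity(self, rng):
        x = rng.normal(size=(20, 8))
        out = combat_correct(x, np.array(["b"] * 20))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_location_effect_removed(self):
        # per-gene scales vary, so the planted +2 shift is identifiable
        # against the EB prior rather than being absorbed into its mean
        rng = np.random.default_rng(0)
        g, n = 30, 500
        mu = rng.normal(0, 1, g)
        sd = rng.uniform(0.5, 2.0, g)
        x1 = rng.normal(mu, sd, size=(n, g))
        x2 = rng.normal(mu + 2.0, sd, size=(n, g))
        x = np.vstack([x1, x2])
        batches = np.array(["a"] * n + ["b"] * n)
        out = combat_correct(x, batches)
        diff = out[:n].mean(axis=0) - out[n:].mean(axis=0)
        assert np.abs(diff).max() < 0.05

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(30, 6))
        batches = np.array(["a"] * 15 + ["b"] * 15)
        out = combat_correct(x, batches)
        perm = rng.permutation(30)
        out_p = combat_correct(x[perm], batches[perm])
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_pooled_mean_preserved(self, rng):
        x = rng.normal(2.0, 1.0, size=(80, 12))
        batches = np.array(["a"] * 30 + ["b"] * 50)
        out = combat_correct(x, batches)
        np.testing.assert_allclose(out.mean(axis=0), x.mean(axis=0), atol=1e-6)

    def test_one_cell_batch_errors(self, rng):
        x = rng.normal(size=(5, 4))
        with pytest.raises(FeatureError, match="fewer than 2"):
            fit_combat(x, np.array(["a", "a", "a", "a", "b"]))


class TestTSVD:
    def test_exact_rank_reconstruction(self, rng):
        a = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 10))
        comps, scores = fit_tsvd(a, 3)
        np.testing.assert_allclose(scores @ comps.T, a, atol=1e-8)

    def test_eigen_oracle(self):
        # oracle: dense eigendecomposition of X^T X
        rng = np.random.default_rng(1)
        x = rng.normal(size=(120, 30))
        comps, scores = fit_tsvd(x, 10)
        sv2 = (scores ** 2).sum(axis=0)
        eig = np.sort(np.linalg.eigvalsh(x.T @ x))[::-1][:10]
        np.testing.assert_allclose(np.sort(sv2)[::-1], eig, rtol=1e-6)

    def test_orthonormal_loadings(self, rng):
        comps, _ = fit_tsvd(rng.normal(size=(50, 20)), 8)
        np.testing.assert_allclose(comps.T @ comps, np.eye(8), atol=1e-8)

    def test_sign_convention(self, rng):
        comps, _ = fit_tsvd(rng.normal(size=(40, 15)), 5)
        for j in range(5):
            assert comps[np.abs(comps[:, j]).argmax(), j] > 0

    def test_explained_variance_monotone(self, rng):
        x = rng.normal(size=(60, 25))
        prev = -1.0
        for k in (2, 5, 10, 20):
            _, scores = fit_tsvd(x, k)
            ev = (scores ** 2).sum()
            assert ev >= prev
            prev = ev

    def test_rank_exceeded_errors(self, rng):
        a = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 10))
        with pytest.raises(FeatureError, match="rank"):
            fit_tsvd(a, 5)


class TestFA:
    def test_planted_subspace_recovery(self):
        rng = np.random.default_rng(0)
        n, g, k = 2000, 40, 5
        lam = rng.normal(size=(g, k))
        z = rng.normal(size=(n, k))
        x = z @ lam.T + 0.3 * rng.normal(size=(n, g))
        params, _ = fit_fa(x, k)
        angles = subspace_angles(params.loadings, lam)
        assert np.degrees(angles.max()) < 5.0

    def test_isotropic_noise_loglik_gain_small(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 15))
        params, _ = fit_fa(x, 1)
        # k=0 oracle: independent diagonal-Gaussian log-likelihood
        var0 = x.var(axis=0)
        ll0 = -0.5 * (np.log(2 * np.pi * var0).sum() + 15)
        lam, psi, mu = params.loadings, params.noise_variance, params.mean
        cov = lam @ lam.T + np.diag(psi)
        xc = x - mu
        sign, logdet = np.linalg.slogdet(cov)
        ll1 = -0.5 * (
            15 * np.log(2 * np.pi) + logdet + np.mean(np.sum(xc @ np.linalg.inv(cov) * xc, axis=1))
        )
        assert ll1 - ll0 < 0.1  # per-sample gain on pure noise is negligible

    def test_gene_permutation_equivariance_of_scores(self, rng):
        x = rng.normal(size=(300, 3)) @ rng.normal(size=(3, 12)) + 0.3 * rng.normal(
            size=(300, 12)
        )
        _, s1 = fit_fa(x, 3)
        perm = rng.permutation(12)
        _, s2 = fit_fa(x[:, perm], 3)
        assert subspace_angles(s1, s2).max() < 1e-6

    def test_k_too_large(self, rng):
        with pytest.raises(FeatureError):
            fit_fa(rng.normal(size=(50, 8)), 8)

    def test_nonconvergence_raises_with_count(self, rng):
        x = rng.normal(size=(200, 20)) @ rng.normal(size=(20, 20))
        with pytest.raises(FAConvergenceError) as ei:
            fit_fa(x, 5, max_iter=2, tol=1e-12)
        assert ei.value.n_iter == 2


class TestAssembledTransform:
    def test_default_width_is_1030(self):
        rng = np.random.default_rng(0)
        n, g = 400, 560
        z = rng.gamma(2.0, 1.0, size=(n, 200))
        lam = rng.gamma(2.0, 0.1, size=(g, 200))
        x = np.log1p(z @ lam.T + rng.gamma(1.0, 0.5, size=(n, g)))
        tf = fit_feature_transform(x, np.array(["b"] * n), FeatureConfig())
        assert tf.output_dim == 550 + 300 + 180 == 1030
        fm = tf.apply(x, np.array(["b"] * n))
        assert fm.width == 1030

    def test_blocks_zscored_on_fitting_set(self, rng):
        x = rng.random((120, 40))
        cfg = FeatureConfig(n_hvg=10, k_tsvd=8, k_fa=5)
        tf = fit_feature_transform(x, np.array(["b"] * 120), cfg)
        fm = tf.apply(x, np.array(["b"] * 120))
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(fm.values.std(axis=0), 1.0, atol=1e-6)

    def test_separate_application_matches_joint(self, rng):
        ref = rng.random((80, 30)) + 0.1
        qry = rng.random((40, 30)) + 0.1
        joint = np.vstack([ref, qry])
        batches = np.array(["r"] * 80 + ["q"] * 40)
        cfg = FeatureConfig(n_hvg=8, k_tsvd=6, k_fa=4)
        tf = fit_feature_transform(joint, batches, cfg)
        fm_joint = tf.apply(joint, batches)
        fm_ref = tf.apply(ref, batches[:80])
        fm_qry = tf.apply(qry, batches[80:])
        np.testing.assert_allclose(fm_joint.values[:80], fm_ref.values, atol=1e-10)
        np.testing.assert_allclose(fm_joint.values[80:], fm_qry.values, atol=1e-10)

    def test_hvg_only_mode(self, rng):
        x = rng.random((50, 20))
        cfg = FeatureConfig(n_hvg=10, k_tsvd=0, k_fa=0)
        tf = fit_feature_transform(x, np.array(["b"] * 50), cfg)
        fm = tf.apply(x, np.array(["b"] * 50))
        assert fm.width == 10
        assert tf.block_boundaries["hvg"] == (0, 10)

    def test_gene_mismatch_errors(self, rng):
        x = rng.random((30, 15))
        tf = fit_feature_transform(x, np.array(["b"] * 30), FeatureConfig(n_hvg=5, k_tsvd=3, k_fa=2))
        with pytest.raises(FeatureError, match="gene count"):
            tf.apply(rng.random((10, 14)), np.array(["b"] * 10))

    def test_save_load_roundtrip(self, tmp_path, rng):
        x = rng.random((60, 20))
        batches = np.array(["a"] * 30 + ["b"] * 30)
        tf = fit_feature_transform(x, batches, FeatureConfig(n_hvg=6, k_tsvd=4, k_fa=3))
        tf.save(tmp_path / "tf.npz")
        from scmtl.features import FeatureTransform

        tf2 = FeatureTransform.load(tmp_path / "tf.npz")
        np.testing.assert_allclose(
            tf.apply(x, batches).values, tf2.apply(x, batches).values, atol=1e-12
        )

    def test_pipeline_deterministic(self, rng):
        x = rng.random((70, 25))
        batches = np.array(["a"] * 35 + ["b"] * 35)
        cfg = FeatureConfig(n_hvg=6, k_tsvd=5, k_fa=3)
        f1 = fit_feature_transform(x, batches, cfg).apply(x, batches).values
        f2 = fit_feature_transform(x, batches, cfg).apply(x, batches).values
        np.testing.assert_array_equal(f1, f2)
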