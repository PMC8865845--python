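import numpy as np
import pytest

import automitoc as am


def _mat(values, prefix="p"):
    p, n = values.shape
    return am.IntensityMatrix([f"{prefix}{i}" for i in range(p)],
                              [f"s{j}" for j in range(n)], values)


class TestFitPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([0.3, -0.7, 1.1])
        model = am.fit_background_pca(_mat(np.outer(u, v)))
        assert model.variance_explained[0] == pytest.approx(1.0)
        assert model.k == 1

    def test_scores_match_dense_eigendecomposition_oracle(self):
        """On a 10x8 instance the scores reproduce the eigendecomposition of
        the sample Gram matrix of probe-centered values (up to sign)."""
        rng = np.random.default_rng(8)
        values = rng.normal(size=(10, 8))
        model = am.fit_background_pca(_mat(values), mode="fixed", k_fixed=7)
        xc = values - values.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(xc.T @ xc)  # 8x8 sample Gram
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(model.variance_explained,
                                   (evals / evals.sum())[:len(model.variance_explained)],
                                   atol=1e-8)
        for c in range(model.k):
            expected = evecs[:, c] * np.sqrt(evals[c])
            got = model.scores[:, c]
            sign = np.sign(expected @ got)
            np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_score_columns_orthogonal(self, small_fit):
        s = small_fit.pc_model.scores
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_sign_canonicalization_is_deterministic(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(12, 6))
        a = am.fit_background_pca(_mat(values))
        b = am.fit_background_pca(_mat(values))
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_zero_variance_rejected(self):
        with pytest.raises(am.ValidationError, match="zero-variance"):
            am.fit_background_pca(_mat(np.ones((4, 4))))


class TestChooseK:
    def test_variance_rule_cumulative(self):
        assert am.choose_k([0.5, 0.25, 0.25], target_fraction=0.70) == 2

    @pytest.mark.parametrize("mode,kw", [("variance", {}), ("elbow", {}),
                                         ("fixed", {"k_fixed": 1})])
    def test_single_component(self, mode, kw):
        assert am.choose_k([1.0], mode=mode, **kw) == 1

    def test_unreachable_target_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="never reaches"):
            assert am.choose_k([0.3, 0.2], target_fraction=0.9) == 2

    def test_elbow_finds_latent_rank(self, default_fit):
        """With 10 latent batch factors the scree elbow lands near 10."""
        k = am.choose_k(default_fit.pc_model.variance_explained, mode="elbow")
        assert 8 <= k <= 15


class TestResidualize:
    def test_k0_model_is_per_probe_centering(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(4, 6))
        m = _mat(values)
        model = am.PCModel(k=0, scores=np.empty((6, 0)),
                           variance_explained=np.array([]), total_fraction=0.0,
                           probe_ids=m.probe_ids, centering=np.zeros(4))
        out = am.residualize(m, model)
        np.testing.assert_allclose(out.values,
                                   values - values.mean(axis=1, keepdims=True),
                                   atol=1e-12)

    def test_probe_equal_to_score_gives_zero_residuals(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(6, 10))
        m = _mat(values)
        model = am.fit_background_pca(m, mode="fixed", k_fixed=2)
        probe = model.scores[:, 0][None, :] * 3.0 + 1.0
        out = am.residualize(_mat(probe, prefix="q"), model)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_matches_statsmodels_ols_oracle_with_missing(self):
        """30-sample probes, k=3: residuals match an independent OLS fit on
        observed entries only."""
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(30, 3))
        values = rng.normal(size=(5, 30))
        values[1, [2, 17]] = np.nan
        values[4, 5] = np.nan
        m = _mat(values)
        model = am.PCModel(k=3, scores=scores, variance_explained=np.ones(3) / 3,
                           total_fraction=1.0, probe_ids=m.probe_ids,
                           centering=np.zeros(5))
        out = am.residualize(m, model)
        X = sm.add_constant(scores)
        for i in range(5):
            obs = ~np.isnan(values[i])
            fit = sm.OLS(values[i, obs], X[obs]).fit()
            np.testing.assert_allclose(out.values[i, obs], fit.resid, atol=1e-10)
        assert np.isnan(out.values[1, 2]) and np.isnan(out.values[4, 5])

    def test_residuals_uncorrelated_with_scores(self, small_fit, small_sim):
        matrix, probes, _, _ = small_sim
        model = small_fit.pc_model
        corrected = small_fit.corrected_mt
        for c in range(model.k):
            score = model.scores[:, c]
            for i in range(0, corrected.n_probes, 7):
                obs = ~corrected.missing_mask[i]
                x = corrected.values[i, obs]
                if x.std() == 0:
                    continue
                r = np.corrcoef(x, score[obs])[0, 1]
                assert abs(r) < 1e-8

    def test_k_too_large_rejected(self):
        m = _mat(np.random.default_rng(1).normal(size=(3, 4)))
        model = am.PCModel(k=4, scores=np.zeros((4, 4)),
                           variance_explained=np.ones(4) / 4, total_fraction=1.0,
                           probe_ids=m.probe_ids, centering=np.zeros(3))
        with pytest.raises(am.ValidationError, match="k="):
            am.residualize(m, model)
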