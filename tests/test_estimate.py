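import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import automitoc as am


def _mt_matrix(values):
    p, n = values.shape
    return am.IntensityMatrix([f"m{i}" for i in range(p)],
                              [f"s{j}" for j in range(n)], values)


def _samples(female, age=None):
    n = len(female)
    return am.SampleAnnotation(pd.DataFrame({
        "sex": ["female" if f else "male" for f in female],
        "age": age if age is not None else np.full(n, np.nan),
    }, index=pd.Index([f"s{j}" for j in range(n)], name="sample_id")))


class TestPcaEstimator:
    def test_noise_free_rank_one_recovers_trait_exactly(self):
        rng = np.random.default_rng(30)
        copy = rng.normal(size=40)
        alpha = np.abs(rng.normal(1.0, 0.2, size=6))
        scores = am.estimate_pca(_mt_matrix(np.outer(alpha, copy)))
        r = np.corrcoef(scores, copy)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_matches_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(31)
        values = rng.normal(size=(5, 4))
        scores = am.estimate_pca(_mt_matrix(values))
        xc = values - values.mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        top = evecs[:, -1] * np.sqrt(evals[-1])
        sign = np.sign(top @ scores)
        np.testing.assert_allclose(scores, sign * top, atol=1e-8)

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(32)
        values = rng.normal(size=(6, 5))
        dup = np.hstack([values, values[:, [2]]])
        scores = am.estimate_pca(_mt_matrix(dup))
        assert scores[5] == pytest.approx(scores[2], abs=1e-10)

    def test_too_few_probes_rejected(self):
        with pytest.raises(am.ValidationError, match="2 MT probes"):
            am.estimate_pca(_mt_matrix(np.zeros((1, 5))))


class TestMedianEstimator:
    def test_single_probe_is_identity(self):
        vals = np.array([[0.4, -0.1, 0.9]])
        np.testing.assert_array_equal(am.estimate_median(_mt_matrix(vals)),
                                      vals[0])

    def test_correlates_with_pca_on_simulation(self, small_fit, small_sim):
        _, _, _, truth = small_sim
        med = am.estimate_median(small_fit.corrected_mt)
        pca = small_fit.estimates.mtdna_cn
        r = np.corrcoef(med, pca)[0, 1]
        assert abs(r) >= 0.8

    def test_pca_at_least_as_concordant_with_truth(self, small_fit, small_sim):
        _, _, _, truth = small_sim
        med = am.estimate_median(small_fit.corrected_mt)
        r_med = abs(np.corrcoef(med, truth.true_copy)[0, 1])
        r_pca = abs(np.corrcoef(small_fit.estimates.mtdna_cn, truth.true_copy)[0, 1])
        assert r_pca >= r_med


class TestAlignSign:
    def test_negative_sex_association_flips(self):
        rng = np.random.default_rng(33)
        n = 200
        female = rng.random(n) < 0.5
        scores = -0.5 * female + rng.normal(0, 0.5, n)
        out, flipped, cov = am.align_sign(scores, _samples(female))
        assert flipped and cov == "sex"
        np.testing.assert_array_equal(out, -scores)

    def test_positive_sex_association_unchanged(self):
        rng = np.random.default_rng(34)
        n = 200
        female = rng.random(n) < 0.5
        scores = 0.5 * female + rng.normal(0, 0.5, n)
        out, flipped, cov = am.align_sign(scores, _samples(female))
        assert not flipped and cov == "sex"
        np.testing.assert_array_equal(out, scores)

    def test_age_fallback_expects_negative_direction(self):
        rng = np.random.default_rng(35)
        n = 200
        age = rng.uniform(40, 70, n)
        scores = 0.05 * age + rng.normal(0, 0.2, n)  # rises with age: flip
        samples = am.SampleAnnotation(pd.DataFrame({
            "sex": ["unknown"] * n, "age": age,
        }, index=pd.Index([f"s{j}" for j in range(n)], name="sample_id")))
        out, flipped, cov = am.align_sign(scores, samples)
        assert cov == "age" and flipped

    def test_no_usable_covariate_warns(self):
        samples = am.SampleAnnotation(pd.DataFrame({
            "sex": ["unknown"] * 5, "age": [np.nan] * 5,
        }, index=pd.Index([f"s{j}" for j in range(5)], name="sample_id")))
        with pytest.warns(UserWarning, match="sign"):
            out, flipped, cov = am.align_sign(np.arange(5.0), samples)
        assert cov == "none" and not flipped


class TestStandardize:
    def test_closed_form(self):
        out = am.standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.224744871391589, 0.0,
                                         1.224744871391589], atol=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance(self, xs, a, b):
        x = np.asarray(xs)
        if x.std(ddof=0) < 1e-6:
            return
        np.testing.assert_allclose(am.standardize(a * x + b), am.standardize(x),
                                   atol=1e-6)

    def test_output_is_standard(self):
        rng = np.random.default_rng(36)
        out = am.standardize(rng.normal(3, 7, 500))
        assert abs(out.mean()) < 1e-10 and abs(out.std(ddof=0) - 1) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(am.ValidationError, match="zero variance"):
            am.standardize(np.ones(5))


class TestRegions:
    def _annot(self, positions):
        ids = [f"m{i}" for i in range(len(positions))]
        return ids, am.ProbeAnnotation(pd.DataFrame({
            "chromosome": ["MT"] * len(positions),
            "position": positions,
            "maf": 0.0, "call_rate": 1.0, "gc_fraction": 0.45,
        }, index=pd.Index(ids, name="probe_id")))

    def test_printed_boundaries_honored_including_gap(self):
        """6425 ends region 1, 6526 starts region 2; 6426-6525 is a literal
        gap: probes there belong to no window."""
        positions = [6425, 6426, 6525, 6526, 11947, 11948, 16569, 1]
        ids, probes = self._annot(positions)
        rng = np.random.default_rng(37)
        m = am.IntensityMatrix(ids, [f"s{j}" for j in range(50)],
                               rng.normal(size=(8, 50)))
        female = rng.random(50) < 0.5
        with pytest.warns(UserWarning, match="no region"):
            ests = am.estimate_by_region(m, probes, _samples(female))
        by_label = {e.region_label: e for e in ests}
        assert by_label["MT:1-6425"].n_mt_probes_used == 2  # 6425 and 1
        assert by_label["MT:6526-11947"].n_mt_probes_used == 2  # 6526, 11947
        assert by_label["MT:11948-16569"].n_mt_probes_used == 2  # 11948, 16569

    def test_identity_partition_equals_full_estimate(self):
        rng = np.random.default_rng(38)
        positions = list(rng.choice(16569, size=10, replace=False) + 1)
        ids, probes = self._annot(positions)
        n = 60
        copy = rng.normal(size=n)
        values = np.abs(rng.normal(1, 0.2, 10))[:, None] * copy[None, :] \
            + rng.normal(0, 0.3, (10, n))
        m = am.IntensityMatrix(ids, [f"s{j}" for j in range(n)], values)
        female = rng.random(n) < 0.5
        samples = _samples(female, age=rng.uniform(40, 70, n))
        full = am.derive_estimates(m, samples)
        regioned = am.estimate_by_region(m, probes, samples,
                                         regions=[("all", 1, 16569)])
        assert len(regioned) == 1
        np.testing.assert_allclose(regioned[0].mtdna_cn, full.mtdna_cn,
                                   atol=1e-10)

    def test_sparse_window_skipped_with_warning(self):
        ids, probes = self._annot([100, 200, 7000])
        rng = np.random.default_rng(39)
        m = am.IntensityMatrix(ids, [f"s{j}" for j in range(40)],
                               rng.normal(size=(3, 40)))
        female = rng.random(40) < 0.5
        with pytest.warns(UserWarning, match="skipped"):
            ests = am.estimate_by_region(m, probes, _samples(female))
        labels = [e.region_label for e in ests]
        assert "MT:6526-11947" not in labels and "MT:1-6425" in labels


def test_estimates_invariant_to_input_ordering(small_sim):
    matrix, probes, samples, _ = small_sim
    from conftest import small_pipeline_config
    rng = np.random.default_rng(40)
    base = am.AutoMitoC(matrix, probes, samples,
                        config=small_pipeline_config()).fit()
    pperm = rng.permutation(matrix.n_probes)
    sperm = rng.permutation(matrix.n_samples)
    shuffled = am.IntensityMatrix(matrix.probe_ids[pperm],
                                  matrix.sample_ids[sperm],
                                  matrix.values[np.ix_(pperm, sperm)])
    other = am.AutoMitoC(shuffled, probes, samples,
                         config=small_pipeline_config()).fit()
    lookup = {s: v for s, v in zip(other.estimates.sample_ids,
                                   other.estimates.mtdna_cn)}
    reordered = np.array([lookup[s] for s in base.estimates.sample_ids])
    np.testing.assert_allclose(reordered, base.estimates.mtdna_cn, atol=1e-8)
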