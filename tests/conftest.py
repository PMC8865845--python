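import numpy as np
import pandas as pd
import pytest

import automitoc as am


@pytest.fixture
def tiny_matrix():
    """4 probes (3 autosomal + 1 MT) x 3 samples, one missing cell."""
    values = np.array([
        [0.1, -0.2, 0.3],
        [0.0, 0.5, np.nan],
        [-0.4, 0.1, 0.2],
        [1.0, -1.0, 0.0],
    ])
    return am.IntensityMatrix(["p1", "p2", "p3", "mt1"], ["s1", "s2", "s3"], values)


@pytest.fixture
def tiny_probes():
    return am.ProbeAnnotation(pd.DataFrame({
        "chromosome": ["1", "2", "22", "chrM"],
        "position": [100, 200, 300, 4000],
        "maf": [0.005, 0.002, 0.009, 0.0],
        "call_rate": [0.99, 0.98, 1.0, 1.0],
        "gc_fraction": [0.4, 0.5, 0.6, 0.45],
    }, index=pd.Index(["p1", "p2", "p3", "mt1"], name="probe_id")))


@pytest.fixture
def tiny_samples():
    return am.SampleAnnotation(pd.DataFrame({
        "sex": ["female", "male", "unknown"],
        "age": [55.0, 63.0, np.nan],
    }, index=pd.Index(["s1", "s2", "s3"], name="sample_id")))


def small_config(seed=7, **kw):
    """Desk-scale simulation: everything the default has, 20x smaller."""
    defaults = dict(n_samples=300, n_auto_probes=600, n_mt_probes=40,
                    k_batch=4, n_numt_probes=12, n_sex_probes=6, seed=seed)
    defaults.update(kw)
    return am.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return am.simulate_dataset(small_config())


def small_pipeline_config(**kw):
    defaults = dict(waviness_max=None, min_autosomal_probes=100)
    defaults.update(kw)
    return am.PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    matrix, probes, samples, truth = small_sim
    model = am.AutoMitoC(matrix, probes, samples, config=small_pipeline_config())
    return model.fit()


# --- study-scale fixtures shared by the acceptance tests -------------------

@pytest.fixture(scope="session")
def default_sim():
    return am.simulate_dataset(am.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_sim):
    matrix, probes, samples, _ = default_sim
    cfg = am.PipelineConfig(waviness_max=None, regions="thirds")
    return am.AutoMitoC(matrix, probes, samples, config=cfg).fit()


@pytest.fixture(scope="session")
def default_fit_no_crosshyb(default_sim):
    matrix, probes, samples, _ = default_sim
    cfg = am.PipelineConfig(waviness_max=None, crosshyb_enabled=False)
    return am.AutoMitoC(matrix, probes, samples, config=cfg).fit()
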