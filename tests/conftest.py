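import numpy as np
import pytest

import omicsgp as og


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_matrix(values, layer="transcriptomic", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return og.FeatureMatrix(
        line_ids=[f"L{i + 1:03d}" for i in range(n)],
        feature_ids=[f"{prefix}{j + 1}" for j in range(p)],
        values=values,
        layer=layer,
    )


def random_psd_kernel(rng, n, ids=None):
    A = rng.standard_normal((n, n + 2))
    K = A @ A.T / (n + 2)
    ids = ids or [f"L{i + 1:03d}" for i in range(n)]
    return og.KernelMatrix(line_ids=ids, values=K, recipe="test")


@pytest.fixture(scope="session")
def small_dataset():
    """Linked synthetic dataset small enough for repeated MCMC fits."""
    cfg = og.SimulationConfig(
        n_lines=60, p_markers=200, p_transcripts=150, p_metabolites=100,
        n_traits=2, seed=7,
    )
    dataset, truth = og.simulate_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def small_m4_kernels(small_dataset):
    dataset, _ = small_dataset
    spec = og.get_model_spec("M4")
    bases = og.build_base_kernels(dataset, og.required_bases([spec]))
    return og.KernelFactory(bases).materialize(spec), spec
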