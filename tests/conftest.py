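import numpy as np
import pytest

from kprofiles import ExpressionMatrix, SimulationSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with hand-readable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [0.5, 0.5, 0.5, 0.5],
        ]
    )
    return ExpressionMatrix(values, ("g1", "g2", "g3"), ("s1", "s2", "s3", "s4"))


@pytest.fixture
def small_structured():
    """Two zero-noise hidden-factor clusters plus a few noise genes."""
    spec = SimulationSpec(
        m_clusters=2,
        genes_per_cluster=12,
        n_samples=40,
        n_noise_genes=6,
        noise_sd=0.0,
        seed=7,
    )
    return simulate(spec)
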