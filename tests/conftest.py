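import numpy as np
import pytest

from stclust import ExpressionMatrix, LabelSet, SpatialCoords
from stclust.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic tissue shared by fast structural tests."""
    return generate_dataset(
        SyntheticConfig(
            n_cells=200,
            n_domains=3,
            n_localized_types=3,
            n_dispersed_types=2,
            n_sv_genes=12,
            n_hv_genes=12,
            n_noise_genes=24,
            seed=7,
        )
    )


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = rng.poisson(3.0, size=(8, 5)).astype(float)
    return ExpressionMatrix(
        values,
        np.array([f"c{i}" for i in range(8)]),
        np.array([f"g{j}" for j in range(5)]),
        layer="raw",
    )


@pytest.fixture
def line_coords():
    """Four points on a line: the worked spatial-metric instance."""
    return SpatialCoords(
        np.array(["c0", "c1", "c2", "c3"]),
        np.array([0.0, 1.0, 2.1, 3.0]),
        np.zeros(4),
    )


@pytest.fixture
def line_labels():
    return LabelSet(np.array(["c0", "c1", "c2", "c3"]), np.array(["A", "B", "B", "B"]))
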