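import numpy as np
import pytest

from simplicomplex import ExpressionMatrix, ScenarioSpec, make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples with distinct rows."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 1.0, 3.0, 2.0],
            [0.0, 10.0, 5.0, 5.0],
        ]
    )
    return ExpressionMatrix(
        values=values,
        gene_ids=["TP53", "BRCA1", "MYC"],
        sample_ids=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture(scope="session")
def triangle_cluster():
    """Noiseless samples from a single triangle in 40 dims (one branch of
    scenario C restricted to its own support), with the true vertices."""
    spec = ScenarioSpec(
        name="custom",
        subsimplex_vertex_sets=[[0, 1, 2]],
        n_samples=250,
        ambient_dim=40,
        noise_level=0.0,
        seed=7,
    )
    em, truth = make_scenario(spec)
    return em, truth


@pytest.fixture(scope="session")
def scenario_c_small():
    """Two triangles joined at a point, desk-scale, low noise."""
    spec = ScenarioSpec(
        name="C_two_triangles_point",
        n_samples=300,
        ambient_dim=500,
        noise_level=0.1,
        seed=42,
    )
    em, truth = make_scenario(spec)
    return spec, em, truth
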