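import numpy as np
import pytest

from maskgnn.graph import BrainGraph, build_adjacency
from maskgnn.model import GraphSample, init_params
from maskgnn.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph_sample(rng, q=5, d_in=None, d_c=3, n_out=1, density=0.5):
    """A random small sample + parameter set for model-level tests."""
    d_in = d_in or q
    conn = rng.uniform(0, 1, size=(q, q))
    conn = (conn + conn.T) / 2
    adj = build_adjacency(conn, k=max(1, int(density * q)), threshold=0.001)
    x = rng.normal(size=(q, d_in))
    c = rng.uniform(0, 1, size=(q, d_c))
    graph = BrainGraph(adjacency=adj, node_features=x)
    label = rng.normal(size=n_out)
    return GraphSample(graph=graph, as_features=c, label=label, subject_id="s")


def small_params(rng, q=5, d_in=None, d_c=3, h1=4, h2=3, n_out=1):
    return init_params(
        rng, n_nodes=q, d_in=d_in or q, d_c=d_c, hidden1=h1, hidden2=h2, n_outputs=n_out
    )


@pytest.fixture
def tiny_sample(rng):
    return random_graph_sample(rng)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small regression cohort with planted FC edges."""
    spec = SyntheticCohortSpec(
        n_subjects=40,
        n_rois=10,
        n_timepoints=120,
        planted_edges=((0, 5), (2, 7)),
        noise_sd=0.05,
        seed=77,
    )
    return generate_cohort(spec)
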