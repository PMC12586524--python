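import numpy as np
import pytest

from fedgat.config import ExperimentConfig
from fedgat.graph_data import ClientShard, FederatedDataset, LabelSpace, MultiLabelGraph
from fedgat.synthetic_data import SyntheticSpec, generate


def make_graph(gid, adjacency, labels, d_x=3, seed=0):
    A = np.asarray(adjacency, dtype=float)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((A.shape[0], d_x))
    return MultiLabelGraph(gid, A, x, np.asarray(labels))


TRIANGLE = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
PATH2 = [[0, 1], [1, 0]]


@pytest.fixture
def triangle_dataset():
    space = LabelSpace(("tox", "mut"))
    g = make_graph("g0", TRIANGLE, [1, 0])
    return FederatedDataset([ClientShard("c0", [g], space)], space)


@pytest.fixture(scope="session")
def small_spec():
    # scaled-down conditions for unit tests; defaults are exercised in acceptance
    return SyntheticSpec(K=4, graphs_per_client=12, nodes_range=(8, 14), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate(small_spec, seed=11)


@pytest.fixture
def fast_config():
    cfg = ExperimentConfig()
    cfg.ae.epochs = 8
    cfg.federation.rounds = 2
    cfg.federation.local_epochs = 1
    cfg.federation.batch_size = 8
    cfg.backbone.hidden = (16, 16)
    cfg.backbone.heads = (2, 2, 1)
    cfg.backbone.head_hidden = 16
    cfg.ae.hidden_dim = 8
    cfg.ae.heads = 2
    cfg.labels.embedding_dim = 16
    cfg.spectral.M = 4
    cfg.spectral.N_max = 16
    return cfg
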