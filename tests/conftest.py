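import numpy as np
import pandas as pd
import pytest

from fflpipe import PipelineConfig, SyntheticSpec, generate_bundle
from fflpipe.meta_deg import ExpressionStudy


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(rng_seed=7)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The default synthetic input bundle (seed 7), generated once."""
    root = tmp_path_factory.mktemp("fixture")
    return generate_bundle(SyntheticSpec(seed=7), root)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


@pytest.fixture
def small_study() -> ExpressionStudy:
    """3 genes x 6 samples, one study, case mean = control mean + 1 for g1."""
    data = pd.DataFrame(
        {
            "a": [2.0, 5.0, 1.0],
            "b": [3.0, 5.0, 1.0],
            "c": [4.0, 5.0, 1.0],
            "d": [1.0, 5.0, 1.0],
            "e": [2.0, 5.0, 1.0],
            "f": [3.0, 5.0, 1.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    groups = pd.Series(["case"] * 3 + ["control"] * 3, index=data.columns)
    return ExpressionStudy(study_id="s1", data=data, groups=groups)


@pytest.fixture(scope="session")
def fixture_graph_20():
    """Connected 20-node random graph used for EPC stability checks."""
    import networkx as nx

    rng = np.random.default_rng(20)
    while True:
        graph = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(2**31)))
        if nx.is_connected(graph):
            return graph
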