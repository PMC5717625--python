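import warnings

import numpy as np
import pytest

import desertsem as d
from desertsem import cli_io


@pytest.fixture(scope="session")
def graph():
    return d.canonical_graph()


@pytest.fixture(scope="session")
def design():
    return d.generate_design(9, seed=1)


@pytest.fixture(scope="session")
def truth():
    return d.default_ground_truth()


@pytest.fixture(scope="session")
def tables(design, truth):
    return d.simulate_dataset(design, truth, seed=42)


@pytest.fixture(scope="session")
def frames(tables, graph):
    return cli_io.build_node_frames(tables, graph)


@pytest.fixture(scope="session")
def fits(graph, frames):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {spec.name: d.fit_node(spec, frames[spec.name]) for spec in graph.nodes}


@pytest.fixture(scope="session")
def sem(fits, graph, frames):
    return d.assemble(fits, graph, frames)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
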