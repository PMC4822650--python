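import networkx as nx
import numpy as np
import pytest

from phenowalk import PhenomeWalk, SamplingConfig
from phenowalk.heterogeneous import assemble_network
from phenowalk.ontology import AnnotationTable, OntologyGraph
from phenowalk.simulate import FixtureSpec, make_case


@pytest.fixture(scope="session")
def bundle():
    """Default planted-module fixture bundle."""
    return make_case(FixtureSpec())


@pytest.fixture(scope="session")
def null_bundle():
    """Null fixture: i.i.d. expression scores, no planted module."""
    return make_case(FixtureSpec(planted_module_size=0, rng_seed=7))


@pytest.fixture(scope="session")
def model(bundle):
    return PhenomeWalk(
        bundle.ppi, bundle.ontology, bundle.annotations, bundle.scores,
        bundle.seeds, expressed=bundle.expressed,
        sampling=SamplingConfig(n_samples=10000, rng_seed=1),
    )


@pytest.fixture(scope="session")
def hetnet(model):
    return model.assemble()


@pytest.fixture(scope="session")
def results(model):
    """Full two-stage fit on the default fixture (shared; treat as read-only)."""
    return model.fit(rng_seed=1)


def random_heterogeneous_network(rng: np.random.Generator, max_nodes: int = 50):
    """A small random two-layer network for solver oracle checks."""
    n_genes = int(rng.integers(5, max(6, max_nodes - 10)))
    n_terms = int(rng.integers(2, min(10, max_nodes - n_genes)))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    terms = [f"t{j:02d}" for j in range(n_terms)]
    ppi = nx.Graph()
    # random connected gene layer: spanning chain plus random extras
    order = list(rng.permutation(genes))
    for a, b in zip(order, order[1:]):
        ppi.add_edge(a, b, confidence=float(rng.uniform(0.7, 1.0)))
    for _ in range(n_genes):
        a, b = rng.choice(genes, size=2, replace=False)
        if a != b:
            ppi.add_edge(a, b, confidence=float(rng.uniform(0.7, 1.0)))
    phenome = nx.Graph()
    phenome.add_nodes_from(terms)
    for _ in range(2 * n_terms):
        a, b = rng.choice(terms, size=2, replace=False)
        if a != b:
            phenome.add_edge(a, b, weight=float(rng.uniform(3.0, 6.0)))
    pairs = set()
    for _ in range(max(2, n_genes // 2)):
        pairs.add((str(rng.choice(genes)), str(rng.choice(terms))))
    annotations = AnnotationTable(frozenset(pairs))
    return assemble_network(ppi, phenome, annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def chain_ontology():
    """ROOT <- A <- B."""
    return OntologyGraph.from_parents({"A": {"ROOT"}, "B": {"A"}})


@pytest.fixture()
def diamond_ontology():
    """ROOT <- {A, B} <- C, plus sibling D under both A and B."""
    return OntologyGraph.from_parents(
        {"A": {"ROOT"}, "B": {"ROOT"}, "C": {"A", "B"}, "D": {"A", "B"}}
    )
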