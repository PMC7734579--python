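import numpy as np
import pytest

from genepriority.simulate import ScenarioConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(universe_size=400, candidate_size=60, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-scale scenario (3000 genes, 200 candidates)."""
    return generate_bundle(ScenarioConfig(seed=11))


def random_dag_instance(rng, n_terms=12, n_genes=30, prefix="T"):
    """A random rooted DAG plus a random direct annotation map."""
    from genepriority.ontology import OntologyDAG

    terms = [f"{prefix}{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        for p in rng.choice(i, size=min(1 + int(rng.random() < 0.4), i), replace=False):
            edges.append((terms[i], terms[int(p)]))
    dag = OntologyDAG.from_edges(terms, edges)
    genes = [f"g{i}" for i in range(n_genes)]
    direct = {}
    for g in genes:
        ts = [t for t in terms[1:] if rng.random() < 0.2]
        if ts:
            direct[g] = frozenset(ts)
    return dag, genes, direct
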