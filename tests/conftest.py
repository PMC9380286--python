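import numpy as np
import pytest

from imepp.ontology import GODag
from imepp.synthetic import SyntheticConfig, generate_bundle_data, generate_toy_worked_example


@pytest.fixture(scope="session")
def toy_bundle():
    return generate_toy_worked_example()


@pytest.fixture(scope="session")
def small_bundle():
    # smaller than the benchmark defaults to keep unit tests fast
    cfg = SyntheticConfig(n_nodes=120, n_essential=12, seed=7)
    return generate_bundle_data(cfg)


@pytest.fixture
def chain_dag():
    """A is_a B is_a C, contribution 0.8."""
    dag = GODag()
    dag.add_edge("A", "B", "is_a")
    dag.add_edge("B", "C", "is_a")
    return dag


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> D, all is_a 0.8."""
    dag = GODag()
    dag.add_edge("A", "B", "is_a")
    dag.add_edge("A", "C", "is_a")
    dag.add_edge("B", "D", "is_a")
    dag.add_edge("C", "D", "is_a")
    return dag


def random_dag(rng: np.random.Generator, n_terms: int = 10) -> GODag:
    """Random small DAG: term i may link to any higher-indexed term (acyclic)."""
    dag = GODag()
    names = [f"T{i}" for i in range(n_terms)]
    for t in names:
        dag.add_term(t, aspect="BP")
    for i in range(n_terms - 1):
        parents = rng.choice(range(i + 1, n_terms), size=min(rng.integers(1, 3), n_terms - i - 1), replace=False)
        for j in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            dag.add_edge(names[i], names[int(j)], rel)
    return dag
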