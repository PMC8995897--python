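import numpy as np
import pytest

from infersentppi.ontology import GoGraph, GoTerm

NS = "biological_process"


def make_graph(parents: dict[str, list[tuple[str, str]]]) -> GoGraph:
    """Build a GoGraph from a {term: [(parent, relation), ...]} dict."""
    terms = {
        t: GoTerm(term_id=t, name=t, namespace=NS, parents=sorted(plist))
        for t, plist in parents.items()
    }
    return GoGraph(terms)


def random_dag(rng: np.random.Generator, n_terms: int) -> dict[str, list[tuple[str, str]]]:
    """Random rooted single-namespace DAG as a parent-edge dict.

    Term i may take one or two parents among earlier terms, so the graph
    is acyclic by construction; relations are a random is_a/part_of mix.
    """
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    parents: dict[str, list[tuple[str, str]]] = {ids[0]: []}
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.35 and i >= 2)
        choice = rng.choice(i, size=min(k, i), replace=False)
        plist = []
        for j in sorted(int(c) for c in choice):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            plist.append((ids[j], rel))
        parents[ids[i]] = plist
    return parents


@pytest.fixture
def chain_graph():
    """root -> A -> B -> C, all is_a."""
    return make_graph(
        {
            "GO:0000001": [],
            "GO:0000002": [("GO:0000001", "is_a")],
            "GO:0000003": [("GO:0000002", "is_a")],
            "GO:0000004": [("GO:0000003", "is_a")],
        }
    )


@pytest.fixture
def diamond_graph():
    """root with two children B, C that share a child D."""
    return make_graph(
        {
            "GO:0000001": [],
            "GO:0000002": [("GO:0000001", "is_a")],
            "GO:0000003": [("GO:0000001", "part_of")],
            "GO:0000004": [("GO:0000002", "is_a"), ("GO:0000003", "is_a")],
        }
    )
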