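import networkx as nx
import pytest

from dispheno import (
    AnnotationCorpus,
    OntologyGraph,
    Term,
    toy_fixture,
)


@pytest.fixture(scope="session")
def toy():
    """The documented 6-term toy: (ontology, corpus, definitions)."""
    return toy_fixture()


@pytest.fixture(scope="session")
def toy_onto(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_corpus(toy):
    return toy[1]


def build_ontology(nodes, edges, root, definitions=None):
    """Assemble an OntologyGraph directly from node/edge lists (test helper)."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    terms = {
        n: Term(id=n, name=f"term {n}", definition=(definitions or {}).get(n, ""))
        for n in nodes
    }
    onto = OntologyGraph(terms=terms, graph=g, root=root)
    onto.validate()
    return onto


@pytest.fixture()
def diamond():
    """Root A with two length-2 paths D->B->A and D->C->A."""
    return build_ontology(
        ["A", "B", "C", "D"],
        [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")],
        "A",
    )


def corpus_from_units(gene_units=None, disease_units=None):
    return AnnotationCorpus(
        gene_to_terms={k: frozenset(v) for k, v in (gene_units or {}).items()},
        disease_to_terms={k: frozenset(v) for k, v in (disease_units or {}).items()},
    )
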