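import pytest
from hypothesis import HealthCheck, settings
from rdflib import BNode, Graph, Literal, URIRef

from decorum.client import PollPolicy
from decorum.fixtures.catalogue import build_decoys, build_hello_catalogue
from decorum.fixtures.transport import (InMemoryTransport,
                                        catalogue_ontology_loader)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def hello_catalogue():
    return build_hello_catalogue()

@pytest.fixture
def full_catalogue(hello_catalogue):
    return hello_catalogue.merge(build_decoys())


@pytest.fixture
def transport(hello_catalogue):
    return InMemoryTransport(hello_catalogue)


@pytest.fixture
def ont_loader(full_catalogue):
    return catalogue_ontology_loader(full_catalogue)


@pytest.fixture
def no_sleep_policy():
    return PollPolicy(sleep=lambda s: None)


# -- hypothesis building blocks -------------------------------------------

import hypothesis.strategies as st  # noqa: E402
from rdflib.namespace import XSD  # noqa: E402

iri_terms = st.integers(0, 24).map(lambda i: URIRef(f"http://example.org/t{i}"))
predicate_terms = st.integers(0, 9).map(
    lambda i: URIRef(f"http://example.org/p{i}")
)
bnode_terms = st.integers(0, 5).map(lambda i: BNode(f"b{i}"))
_text = st.text(
    alphabet=st.characters(min_codepoint=32, max_codepoint=126), max_size=10
)
literal_terms = st.one_of(
    _text.map(Literal),
    st.integers(-100, 100).map(lambda i: Literal(i, datatype=XSD.integer)),
    _text.map(lambda s: Literal(s, lang="en")),
)
subject_terms = st.one_of(iri_terms, bnode_terms)
object_terms = st.one_of(iri_terms, bnode_terms, literal_terms)


@st.composite
def rdf_graphs(draw, max_triples=50):
    g = Graph()
    for s, p, o in draw(
        st.lists(st.tuples(subject_terms, predicate_terms, object_terms),
                 max_size=max_triples)
    ):
        g.add((s, p, o))
    return g
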