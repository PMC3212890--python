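"""Fixture catalogues: services + the ontology documents that define them.

A catalogue bundles named service implementations with a local IRI → OWL
document map, so every class IRI a fixture references resolves without a
network, plus a small corpus of canonical invocation/response message
pairs (stored as plain-text RDF under ``data/``, regenerated and compared
by the corpus-integrity test).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from ..description import ServiceDescription
from ..host import ServiceImplementation
from ..vocab import MEDIA_RDFXML
from .hello import (build_hello, build_parameterized_hello,
                    hello_ontology_graph)

DECOY = Namespace("http://sadiframework.org/examples/decoy.owl#")


@dataclass(frozen=True)
class CorpusEntry:
    """One stored invocation/response pair for a named service."""

    service: str
    request_file: str
    request_media: str
    response_file: str
    response_media: str


@dataclass
class FixtureCatalogue:
    services: dict[str, ServiceImplementation] = field(default_factory=dict)
    #: ontology document IRI (no fragment) → parsed document
    ontologies: dict[str, Graph] = field(default_factory=dict)
    messages: dict[str, CorpusEntry] = field(default_factory=dict)

    def add_service(self, name: str, impl: ServiceImplementation):
        self.services[name] = impl

    def merge(self, other: "FixtureCatalogue") -> "FixtureCatalogue":
        return FixtureCatalogue(
            {**self.services, **other.services},
            {**self.ontologies, **other.ontologies},
            {**self.messages, **other.messages},
        )


def _restriction(g: Graph, prop, facet, value):
    from rdflib import BNode
    # deterministic label so generated ontology documents are byte-stable
    r = BNode(f"restr{len(g)}")
    g.add((r, RDF.type, OWL.Restriction))
    g.add((r, OWL.onProperty, prop))
    g.add((r, facet, value))
    return r


def build_decoys(n: int = 5) -> FixtureCatalogue:
    """``n`` services each consuming its own required property and attaching
    its own output property — none of them accepts a merely-named individual,
    so they are pure discovery decoys next to the hello service."""
    cat = FixtureCatalogue()
    doc = Graph()
    doc.bind("decoy", DECOY)
    for i in range(1, n + 1):
        in_cls, out_cls = DECOY[f"In{i}"], DECOY[f"Out{i}"]
        key, attached = DECOY[f"key{i}"], DECOY[f"value{i}"]
        doc.add((in_cls, RDF.type, OWL.Class))
        doc.add((in_cls, RDFS.subClassOf,
                 _restriction(doc, key, OWL.minCardinality,
                              Literal(1, datatype=XSD.nonNegativeInteger))))
        doc.add((out_cls, RDF.type, OWL.Class))
        doc.add((out_cls, RDFS.subClassOf, in_cls))
        doc.add((out_cls, RDFS.subClassOf,
                 _restriction(doc, attached, OWL.someValuesFrom, XSD.string)))
        doc.add((attached, RDF.type, OWL.DatatypeProperty))
        endpoint = URIRef(f"http://sadiframework.org/examples/decoy{i}")
        desc = ServiceDescription(
            name=f"Decoy{i}",
            endpoint=endpoint,
            input_class=in_cls,
            output_class=out_cls,
            description_text=f"Attaches decoy value #{i}.",
            authority="sadiframework.org",
        )

        def annotate(g, root, params, attached=attached, i=i):
            return [(root, attached, Literal(f"decoy-{i}"))]

        cat.add_service(f"decoy{i}",
                        ServiceImplementation(desc, annotate, "sync"))
    cat.ontologies["http://sadiframework.org/examples/decoy.owl"] = doc
    return cat


def build_hello_catalogue(
    include_async: bool = True,
    include_param: bool = True,
    pending_polls: int = 0,
) -> FixtureCatalogue:
    """The hello service family sharing one ontology document.

    The asynchronous variant lives at its own endpoint so both modes can sit
    in one transport; its protocol behaviour is otherwise identical.
    """
    cat = FixtureCatalogue()
    cat.ontologies["http://sadiframework.org/examples/hello.owl"] = (
        hello_ontology_graph()
    )
    cat.add_service("hello", build_hello("sync"))
    if include_async:
        cat.add_service(
            "hello-async",
            build_hello(
                "async",
                endpoint=URIRef("http://sadiframework.org/examples/hello-async"),
            ),
        )
    if include_param:
        cat.add_service("hello-param", build_parameterized_hello("sync"))
    cat.messages["hello"] = CorpusEntry(
        service="hello",
        request_file="hello-input.rdf",
        request_media=MEDIA_RDFXML,
        response_file="hello-output.rdf",
        response_media=MEDIA_RDFXML,
    )
    return cat


def load_corpus_file(name: str) -> bytes:
    """Read a stored corpus document from the packaged data directory."""
    return (
        importlib.resources.files("decorum.fixtures") / "data" / name
    ).read_bytes()
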