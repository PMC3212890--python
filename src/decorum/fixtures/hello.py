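"""The "hello" worked example.

A service that consumes any URI-named individual carrying at least one
``foaf:name`` (input class ``hello:NamedIndividual``) and decorates it with
a ``hello:greeting`` of ``"Hello, <name>!"`` per name value (output class
``hello:GreetedIndividual``; ``greeting`` is a datatype property).  The
greeting predicate is exactly what a registry indexes: the *function* of
the service is to attach it.
"""

from __future__ import annotations

from typing import Optional

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import FOAF, OWL, RDF, RDFS, XSD

from ..description import ServiceDescription
from ..host import ParameterInstance, ServiceImplementation
from ..rdf_core import serialize_graph
from ..vocab import MEDIA_RDFXML

HELLO = Namespace("http://sadiframework.org/examples/hello.owl#")
HELLO_ENDPOINT = URIRef("http://sadiframework.org/examples/hello")
HELLO_PARAM_ENDPOINT = URIRef("http://sadiframework.org/examples/hello-param")
HELLO_INPUT_ROOT = URIRef("http://sadiframework.org/examples/hello-input.rdf#1")

GREETING_TEMPLATE = "Hello, {name}{punctuation}"


def hello_ontology_graph() -> Graph:
    """Input/output classes: NamedIndividual requires >=1 foaf:name;
    GreetedIndividual bears some hello:greeting string."""
    from rdflib import BNode
    g = Graph()
    g.bind("hello", HELLO)
    g.bind("foaf", FOAF)

    def restriction(prop, facet, value):
        r = BNode()
        g.add((r, RDF.type, OWL.Restriction))
        g.add((r, OWL.onProperty, prop))
        g.add((r, facet, value))
        return r

    g.add((HELLO.NamedIndividual, RDF.type, OWL.Class))
    g.add((HELLO.NamedIndividual, RDFS.subClassOf,
           restriction(FOAF.name, OWL.minCardinality,
                       Literal(1, datatype=XSD.nonNegativeInteger))))
    g.add((HELLO.GreetedIndividual, RDF.type, OWL.Class))
    g.add((HELLO.GreetedIndividual, RDFS.subClassOf,
           restriction(HELLO.greeting, OWL.someValuesFrom, XSD.string)))
    g.add((HELLO.greeting, RDF.type, OWL.DatatypeProperty))
    g.add((HELLO.GreetingParameters, RDF.type, OWL.Class))
    g.add((HELLO.punctuation, RDF.type, OWL.DatatypeProperty))
    return g


def hello_description(
    endpoint: URIRef = HELLO_ENDPOINT, async_capable: bool = False
) -> ServiceDescription:
    return ServiceDescription(
        name="Hello",
        endpoint=endpoint,
        input_class=HELLO.NamedIndividual,
        output_class=HELLO.GreetedIndividual,
        description_text="Attaches a greeting to any individual with a name.",
        authority="sadiframework.org",
        async_capable=async_capable,
    )


def _greet(g: Graph, root: URIRef, punctuation: str = "!"):
    for name in sorted(g.objects(root, FOAF.name), key=str):
        yield (root, HELLO.greeting,
               Literal(GREETING_TEMPLATE.format(name=name,
                                                punctuation=punctuation)))


def build_hello(
    mode: str = "sync", endpoint: Optional[URIRef] = None
) -> ServiceImplementation:
    """The greeting service, in synchronous or asynchronous mode."""
    desc = hello_description(endpoint or HELLO_ENDPOINT,
                             async_capable=(mode == "async"))

    def annotate(g: Graph, root: URIRef, params: Optional[ParameterInstance]):
        return _greet(g, root)

    return ServiceImplementation(description=desc, annotate=annotate, mode=mode)


def build_parameterized_hello(
    mode: str = "sync", endpoint: Optional[URIRef] = None
) -> ServiceImplementation:
    """Greeting service with a control parameter: hello:punctuation
    (default "!"), carried by a hello:GreetingParameters node in the
    invocation message."""
    desc = ServiceDescription(
        name="HelloWithPunctuation",
        endpoint=endpoint or HELLO_PARAM_ENDPOINT,
        input_class=HELLO.NamedIndividual,
        output_class=HELLO.GreetedIndividual,
        parameter_class=HELLO.GreetingParameters,
        description_text="Greeting with configurable punctuation.",
        authority="sadiframework.org",
        async_capable=(mode == "async"),
    )

    def annotate(g: Graph, root: URIRef, params: Optional[ParameterInstance]):
        punct = "!"
        if params is not None:
            value = params.first(HELLO.punctuation)
            if value is not None:
                punct = str(value)
        return _greet(g, root, punct)

    return ServiceImplementation(description=desc, annotate=annotate, mode=mode)


def hello_invocation_graph(
    names: tuple[str, ...] = ("Guy Incognito",),
    roots: Optional[tuple[URIRef, ...]] = None,
) -> Graph:
    """The invocation message: typed root(s) with foaf:name value(s)."""
    roots = roots or tuple(
        HELLO_INPUT_ROOT if i == 0
        else URIRef(f"http://sadiframework.org/examples/hello-input.rdf#{i + 1}")
        for i in range(len(names))
    )
    g = Graph()
    g.bind("hello", HELLO)
    g.bind("foaf", FOAF)
    for root, name in zip(roots, names):
        g.add((root, RDF.type, HELLO.NamedIndividual))
        g.add((root, FOAF.name, Literal(name)))
    return g


def hello_invocation_message(media_type: str = MEDIA_RDFXML) -> bytes:
    """The canonical single-root invocation body, serialized."""
    return serialize_graph(hello_invocation_graph(), media_type)
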