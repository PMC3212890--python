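"""Service-interface documents.

A service endpoint answers HTTP GET with an RDF document describing itself:
an instance of the myGrid/Moby ``serviceDescription`` class carrying exactly
one operation, whose input and output parameters point at the OWL classes
that define what the service consumes and produces.  An optional secondary
parameter points at the class whose instances carry control parameters.

The parser is strict: zero or several description nodes, several operations,
or a missing input/output class are errors, never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import RDF

from .errors import DescriptionError
from . import vocab as V


@dataclass(frozen=True)
class ServiceDescription:
    """One service, one operation: what it eats, what it adds."""

    name: str
    endpoint: URIRef
    input_class: URIRef
    output_class: URIRef
    description_text: str = ""
    parameter_class: Optional[URIRef] = None
    authority: str = ""
    #: advisory only — the protocol is self-describing (202 vs 200 at POST)
    async_capable: bool = False

    def __post_init__(self):
        for slot in ("endpoint", "input_class", "output_class"):
            v = getattr(self, slot)
            if not isinstance(v, URIRef) or ":" not in str(v):
                raise DescriptionError(f"{slot} must be an absolute IRI, got {v!r}")

    def with_endpoint(self, endpoint: URIRef) -> "ServiceDescription":
        return replace(self, endpoint=endpoint)


def _one(g: Graph, subject, predicate, what: str):
    values = list(g.objects(subject, predicate))
    if len(values) != 1:
        raise DescriptionError(
            f"expected exactly one {what}, found {len(values)}"
        )
    return values[0]


def parse_description(g: Graph) -> ServiceDescription:
    """Extract the single service description from ``g``."""
    nodes = list(g.subjects(RDF.type, V.SERVICE_DESCRIPTION))
    if len(nodes) != 1:
        raise DescriptionError(
            f"expected exactly one serviceDescription node, found {len(nodes)}"
        )
    node = nodes[0]
    if not isinstance(node, URIRef):
        raise DescriptionError("serviceDescription node must be the endpoint IRI")
    operation = _one(g, node, V.HAS_OPERATION, "operation")

    def param_class(predicate, what, required):
        params = list(g.objects(operation, predicate))
        if not params:
            if required:
                raise DescriptionError(f"operation is missing its {what}")
            return None
        if len(params) > 1:
            raise DescriptionError(f"operation has {len(params)} {what}s")
        cls = g.value(params[0], V.OBJECT_TYPE)
        if not isinstance(cls, URIRef):
            raise DescriptionError(f"{what} does not name an objectType class")
        return cls

    name = g.value(node, V.SERVICE_NAME_TEXT)
    text = g.value(node, V.SERVICE_DESCRIPTION_TEXT)
    authority = g.value(node, V.AUTHORITY)
    async_flag = g.value(node, V.ASYNC_CAPABLE)
    return ServiceDescription(
        name=str(name) if name is not None else "",
        endpoint=node,
        input_class=param_class(V.INPUT_PARAMETER, "input parameter", True),
        output_class=param_class(V.OUTPUT_PARAMETER, "output parameter", True),
        parameter_class=param_class(V.SECONDARY_PARAMETER, "secondary parameter", False),
        description_text=str(text) if text is not None else "",
        authority=str(authority) if authority is not None else "",
        async_capable=bool(async_flag is not None and async_flag.toPython()),
    )


def emit_description(d: ServiceDescription) -> Graph:
    """Serialize ``d`` as an interface document; inverse of :func:`parse_description`."""
    g = Graph()
    g.bind("mygrid", V.MYGRID)
    node = d.endpoint
    g.add((node, RDF.type, V.SERVICE_DESCRIPTION))
    if d.name:
        g.add((node, V.SERVICE_NAME_TEXT, Literal(d.name)))
    if d.description_text:
        g.add((node, V.SERVICE_DESCRIPTION_TEXT, Literal(d.description_text)))
    if d.authority:
        g.add((node, V.AUTHORITY, Literal(d.authority)))
    if d.async_capable:
        g.add((node, V.ASYNC_CAPABLE, Literal(True)))
    op = BNode()
    g.add((node, V.HAS_OPERATION, op))
    for predicate, cls in (
        (V.INPUT_PARAMETER, d.input_class),
        (V.OUTPUT_PARAMETER, d.output_class),
        (V.SECONDARY_PARAMETER, d.parameter_class),
    ):
        if cls is None:
            continue
        param = BNode()
        g.add((op, predicate, param))
        g.add((param, V.OBJECT_TYPE, cls))
    return g
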