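"""Client side: fetch descriptions, validate, invoke, and split outputs.

Nothing here is required to talk to a service — any HTTP POST of RDF will do
— this module is the convenience layer: it completes asynchronous
invocations transparently (following ``rdfs:isDefinedBy`` polling URLs,
honouring ``Retry-After`` across 302 responses) and maps multiplexed outputs
back to inputs purely by root-IRI identity, which the protocol guarantees.

Transports are injectable objects with ``get(iri)`` and
``post(iri, body, content_type, accept)`` returning
:class:`~decorum.host.HttpResponse`; tests use an in-memory transport,
production uses the socket transport in :mod:`decorum.http_transport`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

from rdflib import BNode, Graph, URIRef
from rdflib.namespace import RDFS

from .description import ServiceDescription, parse_description
from .errors import InvocationError, TransportError
from .host import DEFAULT_RETRY_AFTER_S, HttpResponse
from .owl_model import Ontology, satisfies
from .rdf_core import (extract_typed_roots, graph_union, parse_graph,
                       serialize_graph)
from .vocab import MEDIA_RDFXML


class Transport(Protocol):
    def get(self, iri: str) -> HttpResponse: ...

    def post(
        self, iri: str, body: bytes, content_type: str, accept: Optional[str] = None
    ) -> HttpResponse: ...


@dataclass
class PollPolicy:
    """How patiently to chase an asynchronous result."""

    max_polls: int = 60
    default_retry_after_s: float = float(DEFAULT_RETRY_AFTER_S)
    #: injectable so tests never actually sleep
    sleep: Callable[[float], None] = time.sleep


@dataclass
class InvocationResult:
    merged: Graph
    per_root: dict[URIRef, Graph]
    failures: dict[URIRef, str] = field(default_factory=dict)
    #: response triples not reachable from any input root
    orphans: Graph = field(default_factory=Graph)

    @property
    def ok(self) -> bool:
        return not self.failures


def fetch_description(endpoint: URIRef, transport: Transport) -> ServiceDescription:
    """GET the endpoint and parse its interface document."""
    resp = transport.get(str(endpoint))
    if resp.status != 200:
        raise TransportError(
            f"GET {endpoint} returned status {resp.status}, expected 200"
        )
    g = parse_graph(resp.body, resp.media_type or MEDIA_RDFXML)
    return parse_description(g)


OntologyLoader = Callable[[URIRef], Ontology]


def validate_input(
    g: Graph, d: ServiceDescription, ont_loader: OntologyLoader
) -> list[tuple[URIRef, list]]:
    """Pre-flight check of every typed root against the service's input class.

    Optional: providers extract roots by ``rdf:type`` alone, so validation is
    a client-side aid, not part of the protocol.  Returns one entry per root
    that fails, with its unmet restrictions; an empty list means all roots
    classify.
    """
    ont = ont_loader(d.input_class)
    if d.input_class not in ont.classes:
        raise InvocationError(
            f"input class {d.input_class} not defined by its ontology"
        )
    cls = ont.classes[d.input_class]
    problems = []
    for root in extract_typed_roots(g, d.input_class):
        ok, unmet = satisfies(g, root, cls, ont)
        if not ok:
            problems.append((root, unmet))
    return problems


def map_outputs(
    input_roots: list[URIRef], out: Graph
) -> tuple[dict[URIRef, Graph], Graph]:
    """Partition a response graph among input roots by forward reachability.

    A service attaches its results as properties *of* the input node, so each
    root's share is everything reachable from it along outgoing edges.
    Triples reachable from no root are returned separately.
    """
    mapping: dict[URIRef, Graph] = {}
    claimed: set = set()
    for root in input_roots:
        reachable = {root}
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for _, _, o in out.triples((node, None, None)):
                if isinstance(o, (URIRef, BNode)) and o not in reachable:
                    reachable.add(o)
                    frontier.append(o)
        share = Graph()
        for t in out:
            if t[0] in reachable:
                share.add(t)
                claimed.add(t)
        if len(share):
            mapping[root] = share
    orphans = Graph()
    for t in out:
        if t not in claimed:
            orphans.add(t)
    return mapping, orphans


def _poll(
    transport: Transport, poll_iri: str, policy: PollPolicy
) -> tuple[Optional[Graph], Optional[str]]:
    url = poll_iri
    for _ in range(policy.max_polls):
        try:
            resp = transport.get(url)
        except TransportError as exc:
            return None, f"transport failure while polling {url}: {exc}"
        if resp.status == 200:
            return parse_graph(resp.body, resp.media_type or MEDIA_RDFXML), None
        if resp.status == 302:
            url = resp.header("Location", url)
            retry = resp.header("Retry-After") or None
            policy.sleep(
                float(retry) if retry else policy.default_retry_after_s
            )
            continue
        return None, f"poll of {url} returned status {resp.status}"
    return None, f"poll budget of {policy.max_polls} exhausted for {poll_iri}"


def invoke(
    endpoint: URIRef,
    g: Graph,
    transport: Transport,
    params: Optional[Graph] = None,
    poll_policy: Optional[PollPolicy] = None,
    media_type: str = MEDIA_RDFXML,
) -> InvocationResult:
    """Invoke a service on every typed root of ``g`` and split the response.

    Synchronous (200) responses are split by root immediately; asynchronous
    (202) responses are completed by following each root's polling URL.  A
    control-parameter graph, when given, is merged into the POSTed message
    as an independent subgraph — the invocation is always a single
    non-parameterized POST.
    """
    if len(g) == 0:
        raise InvocationError("refusing to invoke on an empty input graph")
    policy = poll_policy or PollPolicy()
    desc = fetch_description(endpoint, transport)
    roots = extract_typed_roots(g, desc.input_class)
    if not roots:
        raise InvocationError(
            f"input graph has no URI-named root typed {desc.input_class}"
        )
    message = graph_union(g, params) if params is not None else g
    resp = transport.post(
        str(endpoint), serialize_graph(message, media_type), media_type
    )
    per_root: dict[URIRef, Graph] = {}
    failures: dict[URIRef, str] = {}
    orphans = Graph()
    if resp.status in (200, 500):
        out = parse_graph(resp.body, resp.media_type or MEDIA_RDFXML)
        per_root, orphans = map_outputs(roots, out)
        for root in roots:
            if root not in per_root:
                failures[root] = f"no output for root (response status {resp.status})"
    elif resp.status == 202:
        stub = parse_graph(resp.body, resp.media_type or MEDIA_RDFXML)
        for root in roots:
            poll_iri = stub.value(root, RDFS.isDefinedBy)
            if poll_iri is None:
                failures[root] = "202 response carries no isDefinedBy polling URL"
                continue
            result, problem = _poll(transport, str(poll_iri), policy)
            if result is None:
                failures[root] = problem
            else:
                share, extra = map_outputs([root], result)
                per_root[root] = share.get(root, Graph())
                for t in extra:
                    orphans.add(t)
    else:
        for root in roots:
            failures[root] = f"service returned status {resp.status}"
    merged = graph_union(*per_root.values()) if per_root else Graph()
    return InvocationResult(merged, per_root, failures, orphans)
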