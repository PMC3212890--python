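"""In-memory transport: the HTTP contract without sockets.

Routes GETs and POSTs directly to :class:`~decorum.host.ServiceHost`
instances built from a catalogue, serves the catalogue's ontology
documents at their IRIs, and dereferences polling URLs under
``<endpoint>/task/<id>``.  Behaviour is the same as the socket transport on
the shared corpus — asserted by the dual-transport test.
"""

from __future__ import annotations

from typing import Optional

from rdflib import URIRef

from ..errors import OntologyError, TransportError
from ..host import HttpResponse, ServiceHost
from ..owl_model import Ontology, ontology_from_graph
from ..rdf_core import serialize_graph
from ..vocab import MEDIA_RDFXML
from .catalogue import FixtureCatalogue


class InMemoryTransport:
    def __init__(self, catalogue: FixtureCatalogue, pending_polls: int = 0,
                 retry_after_s: int = 5):
        self.catalogue = catalogue
        self.hosts: dict[str, ServiceHost] = {
            str(impl.description.endpoint): ServiceHost(
                impl, pending_polls=pending_polls, retry_after_s=retry_after_s
            )
            for impl in catalogue.services.values()
        }

    def host_for(self, name: str) -> ServiceHost:
        impl = self.catalogue.services[name]
        return self.hosts[str(impl.description.endpoint)]

    def get(self, iri: str) -> HttpResponse:
        if iri in self.hosts:
            return self.hosts[iri].handle_get()
        for endpoint, host in self.hosts.items():
            prefix = endpoint + "/task/"
            if iri.startswith(prefix):
                return host.handle_poll(iri[len(prefix):])
        doc = iri.split("#")[0]
        if doc in self.catalogue.ontologies:
            return HttpResponse(
                200, {"Content-Type": MEDIA_RDFXML},
                serialize_graph(self.catalogue.ontologies[doc], MEDIA_RDFXML),
            )
        raise TransportError(f"unknown endpoint {iri}")

    def post(self, iri: str, body: bytes, content_type: str,
             accept: Optional[str] = None) -> HttpResponse:
        if iri not in self.hosts:
            raise TransportError(f"unknown endpoint {iri}")
        return self.hosts[iri].handle_post(body, content_type, accept)


def catalogue_ontology_loader(catalogue: FixtureCatalogue):
    """An ontology loader resolving class IRIs inside the catalogue's documents."""

    cache: dict[str, Ontology] = {}

    def load(class_iri: URIRef) -> Ontology:
        doc = str(class_iri).split("#")[0]
        if doc not in cache:
            if doc not in catalogue.ontologies:
                raise OntologyError(
                    f"class {class_iri} does not resolve to a known ontology "
                    f"document"
                )
            cache[doc] = ontology_from_graph(catalogue.ontologies[doc])
        return cache[doc]

    return load
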