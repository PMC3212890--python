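"""Pass large data by reference instead of inline.

A node annotated with rdfs:isDefinedBy points at a document that supplies
its missing triples; resolving the reference merges them in.  Services and
clients can therefore exchange lightweight stubs for big records.
"""

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import FOAF, RDFS

from decorum import resolve_by_reference, serialize_graph
from decorum.vocab import MEDIA_N3

node = URIRef("http://example.org/protein/P09416")
doc_iri = "http://example.org/protein/P09416.rdf"

remote = Graph()
remote.add((node, FOAF.name, Literal("P09416")))
remote.add((node, URIRef("http://example.org/vocab#sequenceLength"),
            Literal(417)))

def fetch(iri):
    """Stand-in for HTTP GET: serves the one document we 'host'."""
    print(f"  dereferencing {iri}")
    assert iri == doc_iri
    return serialize_graph(remote, MEDIA_N3), MEDIA_N3

stub = Graph()
stub.add((node, RDFS.isDefinedBy, URIRef(doc_iri)))
print(f"stub graph: {len(stub)} triple(s)")

full = resolve_by_reference(stub, node, fetch, depth_limit=1)
print(f"resolved  : {len(full)} triples")
for triple in sorted(full, key=str):
    print("   ", *triple)
# The stub travelled with one triple; the resolved graph carries the
# record's data, fetched only when (and if) someone needs it.
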