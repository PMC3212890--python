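"""Configure a service through an in-message parameter node.

Invocation is a single non-parameterized POST: configuration travels as an
independent RDF node inside the same message, typed with the parameter
class the service declares in its interface document.
"""

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from decorum import fetch_description, invoke
from decorum.fixtures import (HELLO, HELLO_INPUT_ROOT, InMemoryTransport,
                              hello_invocation_graph)
from decorum.fixtures.catalogue import build_hello_catalogue

transport = InMemoryTransport(build_hello_catalogue())
endpoint = URIRef("http://sadiframework.org/examples/hello-param")

description = fetch_description(endpoint, transport)
print(f"parameter class: {description.parameter_class}")

params = Graph()
node = URIRef("http://example.org/my-settings")
params.add((node, RDF.type, description.parameter_class))
params.add((node, HELLO.punctuation, Literal("?!")))

result = invoke(endpoint, hello_invocation_graph(("Guy Incognito",)),
                transport, params=params)
greeting = next(result.merged.objects(HELLO_INPUT_ROOT, HELLO.greeting))
print(f"greeting       : {greeting}")
# The punctuation setting changed the decoration; with no parameter node
# the service's default ("!") applies.
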