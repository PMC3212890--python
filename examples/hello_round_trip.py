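"""Invoke the greeting service synchronously and inspect the decoration.

The service consumes any URI-named individual with a foaf:name and attaches
a hello:greeting to that same URI — the output root is the input root.
"""

from rdflib import RDF

from decorum import fetch_description, invoke
from decorum.fixtures import (HELLO, HELLO_ENDPOINT, HELLO_INPUT_ROOT,
                              InMemoryTransport, hello_invocation_graph)
from decorum.fixtures.catalogue import build_hello_catalogue

transport = InMemoryTransport(build_hello_catalogue())

description = fetch_description(HELLO_ENDPOINT, transport)
print(f"service     : {description.name} @ {description.endpoint}")
print(f"consumes    : {description.input_class}")
print(f"produces    : {description.output_class}")

result = invoke(HELLO_ENDPOINT, hello_invocation_graph(("Guy Incognito",)),
                transport)
output = result.per_root[HELLO_INPUT_ROOT]
greeting = next(output.objects(HELLO_INPUT_ROOT, HELLO.greeting))
print(f"root in/out : {HELLO_INPUT_ROOT}  (unchanged)")
print(f"greeting    : {greeting}")
print(f"typed as    : {next(output.objects(HELLO_INPUT_ROOT, RDF.type))}")
# The greeting literal is the service's entire function; the preserved root
# IRI is what lets multiplexed outputs be matched back to inputs for free.
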