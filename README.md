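# decorum

Semantic web services that **decorate** RDF graphs — a complete,
offline-testable stack for the annotator style of service common in
bioinformatics data integration, where almost every useful operation is
stateless and transformative: it takes an identified thing (a gene, a
pathway, a protein) and tells you something new about it.

## The model

A service's interface is a pair of OWL-DL classes:

* the **input class** — property restrictions saying what data a consumable
  node must carry (e.g. *at least one `foaf:name`*);
* the **output class** — restrictions describing the predicates the service
  will add (e.g. *some `hello:greeting`*).

The protocol is plain HTTP, no envelope, no scaffolding:

1. `GET endpoint` → an RDF interface document naming the two classes;
2. `POST` an RDF graph containing one or more URI-named roots explicitly
   typed `rdf:type InputClass` (several roots = multiplexing);
3. the service attaches its results as new predicate/value pairs **on the
   same root URIs**, re-types them with the output class, and returns the
   concatenation of the per-root outputs.

Because the root URI is preserved, outputs map back to inputs with no
bookkeeping, and because the *attached properties* —

```
attached(S) = { p : p restricted in Output_S } \ { p : p restricted in Input_S }
```

— are exactly what the service computes, a registry can index services by
predicate and answer "what can I learn about this node?" directly.
Long-running services answer `202` with a per-root `rdfs:isDefinedBy`
polling URL (`302` while pending, `200` with the synchronous-equivalent
graph when done); configuration travels as an independently-typed parameter
node inside the same message; large records travel by reference via
`rdfs:isDefinedBy`.

On top of this sit a property-indexed **registry** (structural
matchmaking: a node matches an input class when its asserted triples
satisfy the restrictions, whatever ontology produced it) and a
**resolver** that answers SELECT queries over a basic graph pattern by
intercepting each predicate, invoking the services that attach it, and
accumulating a query-specific triplestore with per-triple provenance.

## Worked example

```python
from decorum import fetch_description, invoke
from decorum.fixtures import (HELLO, HELLO_ENDPOINT, HELLO_INPUT_ROOT,
                              InMemoryTransport, hello_invocation_graph)
from decorum.fixtures.catalogue import build_hello_catalogue

transport = InMemoryTransport(build_hello_catalogue())
result = invoke(HELLO_ENDPOINT, hello_invocation_graph(("Guy Incognito",)),
                transport)
print(next(result.merged.objects(HELLO_INPUT_ROOT, HELLO.greeting)))
```

prints

```
Hello, Guy Incognito!
```

the greeting the service attached to the unchanged root IRI
`http://sadiframework.org/examples/hello-input.rdf#1`.  Running
`python examples/query_resolution.py` shows the resolver growing a
2-triple seed into a 14-triple store by invoking a discovered 3-service
chain, and ending with the single binding each variable can take; the
other scripts in `examples/` walk the asynchronous protocol, the discovery
menu, control parameters and pass-by-reference, each printing the
intermediate protocol states.

A thin CLI mirrors the library for shell use:
`decorum serve|invoke|register|find|menu|monitor|query --help`.

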