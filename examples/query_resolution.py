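"""Answer a query by building the triplestore it needs on the fly.

A three-step service chain: each service links a Stage_i individual to a
fresh Stage_{i+1} individual.  The resolver intercepts each query
predicate, discovers the service that attaches it, invokes it on the nodes
accumulated so far, and finally matches the pattern over the grown store —
the database required to answer the question is generated by asking it.
"""

from decorum import Registry, resolve
from decorum.fixtures import (InMemoryTransport, SyntheticSpec, build_chain,
                              catalogue_ontology_loader)

fixture = build_chain(SyntheticSpec(chain_length=3, seed=42))
transport = InMemoryTransport(fixture.catalogue)
loader = catalogue_ontology_loader(fixture.catalogue)

registry = Registry()
for impl in fixture.catalogue.services.values():
    registry.register(impl.description.endpoint, transport, loader)

print("query:")
print(fixture.query)
result = resolve(fixture.query, registry, fixture.seed_graph, transport)

print(f"seed triples    : {len(fixture.seed_graph)}")
print(f"store triples   : {len(result.store.graph)} "
      f"(grown by invoking discovered services)")
sources = {s for s in result.store.provenance.values() if s != "seed"}
print(f"services used   : {len(sources)}")
for solution in result.solutions:
    for var, term in sorted(solution.items(), key=lambda kv: str(kv[0])):
        print(f"  ?{var} = {term}")
# One solution: each ?v_i is the individual minted by chain service i, and
# ?lab is the label attached by the final service — none of it existed in
# the seed graph.
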