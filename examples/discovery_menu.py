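"""Discover services by what they can attach to a data node.

A registry indexes every service by its attached properties — the
predicates its output class restricts beyond its input class.  Given a
node, the property menu lists each predicate some consuming service could
attach, the behaviour behind "right-click a node, see its possible
relationships" data-exploration interfaces.
"""

from decorum import Registry
from decorum.fixtures import (HELLO_INPUT_ROOT, InMemoryTransport,
                              catalogue_ontology_loader,
                              hello_invocation_graph)
from decorum.fixtures.catalogue import build_decoys, build_hello_catalogue

catalogue = build_hello_catalogue(include_async=False, include_param=False)
catalogue = catalogue.merge(build_decoys(5))
transport = InMemoryTransport(catalogue)
loader = catalogue_ontology_loader(catalogue)

registry = Registry()
for impl in catalogue.services.values():
    record = registry.register(impl.description.endpoint, transport, loader)
    attached = ", ".join(sorted(str(p).rsplit("#")[-1] for p in record.attached))
    print(f"registered {record.description.name:<8} attaches: {attached}")

node_graph = hello_invocation_graph()
print(f"\nmenu for {HELLO_INPUT_ROOT}:")
for prop, services in registry.property_menu(node_graph, HELLO_INPUT_ROOT).items():
    names = ", ".join(r.description.name for r in services)
    print(f"  {prop}  <- {names}")
# Only the greeting service consumes a merely-named individual, so the menu
# offers exactly one attachable predicate despite six registered services.
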