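"""Walk the asynchronous protocol by hand: 202, then 302, then 200.

A long-running service answers the POST immediately with a 202 whose body
decorates each input root with an rdfs:isDefinedBy polling URL; polling
yields 302 (try again after Retry-After) until the result is ready, at
which point the response is identical to the synchronous one.
"""

from rdflib import RDFS

from decorum import ServiceHost, parse_graph
from decorum.fixtures import HELLO_INPUT_ROOT, build_hello, hello_invocation_message
from decorum.vocab import MEDIA_RDFXML

host = ServiceHost(build_hello("async"), pending_polls=1)

accepted = host.handle_post(hello_invocation_message(), MEDIA_RDFXML)
print(f"POST   -> {accepted.status}  Retry-After: {accepted.header('Retry-After')}s")
stub = parse_graph(accepted.body, accepted.media_type)
poll_iri = str(stub.value(HELLO_INPUT_ROOT, RDFS.isDefinedBy))
print(f"poll URL for root: {poll_iri}")

task_id = poll_iri.rsplit("/", 1)[1]
pending = host.handle_poll(task_id)
print(f"poll 1 -> {pending.status}  (pending; Location points back at the same URL)")

done = host.handle_poll(task_id)
print(f"poll 2 -> {done.status}  (complete)")
for triple in sorted(parse_graph(done.body, done.media_type), key=str):
    print("   ", *triple)
# The final graph is exactly what the synchronous mode would have returned.
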