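# Methods

## The service model and its assumptions

Every service is modelled as a pure annotator: it consumes URI-named RDF
individuals of an OWL input class and returns the *same* URIs decorated
with new predicate/value pairs and re-typed with the output class.  The
stack assumes services are stateless and atomic — invoking the same
message twice yields isomorphic responses — and that input roots are never
blank nodes (a blank node has no URI to preserve, so blank typed subjects
are diagnosed and skipped rather than served).  Graph equality everywhere
is RDF graph isomorphism (blank-node bijection), computed with
`rdflib.compare`; response comparisons are never order- or
serialization-sensitive.

Two wire dialects are accepted, RDF/XML (`application/rdf+xml`) and N3
(`text/rdf+n3`).  These are the conventional media-type strings for the
two serializations; anything else is a protocol error, deliberately
distinct from a malformed payload in a supported dialect.

## Structural classification

Matchmaking decides instance–class membership by checking the class's
property restrictions (and, recursively, those of its defined named
superclasses) directly against asserted triples, with no DL entailment.
This matches the provider-side reality that services locate their roots by
`rdf:type` and must be implementable without a reasoner; `satisfies()` is
nevertheless the single choke point where a full reasoner could be
plugged in later.

Supported OWL subset: `owl:Restriction` with `someValuesFrom`,
`allValuesFrom`, `minCardinality`, `hasValue`; `owl:intersectionOf`;
`rdfs:subClassOf`/`owl:equivalentClass` to named classes.  This covers
every construct the reference examples and behaviours need.  Anything else
(`unionOf`, `complementOf`, max/exact cardinalities, `oneOf`) produces a
load-time warning and is excluded from matchmaking — never a silent drop
and never a silent pass.  Decisions within the subset:

* `someValuesFrom` over a named class accepts a value that is either
  explicitly typed with that class *or* recursively satisfies it
  structurally; a filler class missing from the ontology raises an error.
* `allValuesFrom` is vacuously true when the property is absent; because
  it is non-monotone under graph growth it is excluded from the
  monotonicity property test and covered by the oracle corpus instead.
* `minCardinality` counts distinct RDF terms, so two syntactically
  different literals (`"1"` vs `"1"^^xsd:integer`) count as two.
* Explicit `rdf:type` of the class being checked is *not* a shortcut:
  typing locates roots, restrictions decide membership.
* Datatype fillers are the XSD namespace plus `rdfs:Literal`; a plain
  literal counts as `xsd:string`.
* Cyclic structural dependencies (class A needing a value in A) terminate
  by treating the revisited pair as unestablishable.

The independent check on all of this is a deliberately naive brute-force
membership checker (`decorum.fixtures.oracle`) sharing no code with the
classifier; the suite and the acceptance script require zero disagreements
over generated corpora spanning every restriction kind.

## Protocol parameters

| Parameter | Default | Rationale |
|---|---|---|
| `Retry-After` | 5 s | advisory poll interval in 202/302 responses; any positive value is protocol-valid |
| client poll budget | 60 polls | bounds an invocation against a wedged service; failures are per-root, other roots unaffected |
| async task retention | 3600 s | completed results are deleted afterwards and poll as 404 |
| pass-by-reference depth | 1 | one round of `rdfs:isDefinedBy` dereferencing; each URL fetched at most once, so cycles terminate |
| resolver limits | 50 invocations, 100 inputs/call | caps dynamic store growth; exhaustion flags the result partial rather than failing |

Error statuses follow plain HTTP semantics: 400 for client faults
(unparseable body, no typed root, ambiguous parameter node), 404 for
unknown/expired polling URLs, 500 for provider faults.  In a multiplexed
request a failing root gets a diagnostic triple
(`svc:serviceError "<message>"`) while the other roots' outputs are
returned normally — multiplexing is defined as concatenation of
independent runs — and 500 is reserved for the case where every root
failed.  Extra input triples beyond the matched restrictions are visible
to the provider function but never echoed into the output, which keeps
synchronous and asynchronous responses exactly comparable.

Asynchronous tasks complete lazily at poll time rather than on a
background thread: a host-level `pending_polls` knob (default 0) says how
many polls answer 302 before the computation runs.  This keeps the
202→302→200 sequence deterministic and observable; a production host
would compute in the background and the protocol surface would not change.

## The resolver

Queries are SELECT over one conjunctive basic graph pattern; OPTIONAL,
FILTER and UNION raise an explicit unsupported-feature error.  rdflib's
SPARQL parser supplies parsing and prefix expansion; pattern evaluation is
this package's own conjunctive matcher because it is interleaved with
service invocation (rdflib's full engine serves as the independent oracle
in tests for the seed-only case).  Planning preserves textual order except
where a pattern's subject variable is produced by a later pattern, in
which case the producer is moved first; ties break textually, so plans are
deterministic.  Candidate inputs for a discovered service are the store's
nodes explicitly typed with its input class plus those structurally
satisfying it; candidates are re-typed in the outgoing message because
providers locate roots by type.  Each (service, node) pair is invoked at
most once per resolution, which is the loop-prevention policy; when
several services attach the same predicate all are invoked and their
outputs unioned.  Every non-seed triple in the working store records the
endpoint that produced it.

## What the fixtures emulate — and what they do not

The reference catalogue reproduces the canonical worked example (a
greeting service requiring `foaf:name` and attaching `hello:greeting`,
with the "Guy Incognito" → "Hello, Guy Incognito!" message pair stored as
plain-text RDF under `fixtures/data/` and regenerated by the
corpus-integrity test), a parameterized variant, and decoy services that
consume properties a merely-named node lacks.  Synthetic generators
produce, reproducibly from a seed: linear service chains whose end-to-end
answer is a closed form known to the generator; random catalogues for
index-consistency checks; and labeled matchmaking cases balanced ~50/50
between positives and targeted violations (missing witness, wrong
datatype, short cardinality, wrong `hasValue` term, offending
`allValuesFrom` member).

The in-memory transport implements the full GET/POST/poll contract without
sockets and is held to behavioural parity with the stdlib-based socket
transport by a dual-transport replay test.  What passing tests therefore
do **not** show: behaviour against real network latency, content
negotiation quirks of third-party HTTP stacks, hostile or
schema-violating remote descriptions, and ontologies outside the
supported OWL subset.  Problem sizes were chosen to exercise the
behaviours, not to benchmark: 1,000 matchmaking cases, 100 random
catalogues, chains of length 2–4, multiplexing up to 10 roots.

## Known limitations

* No DL entailment anywhere; data relying on inferred types or property
  hierarchies will not match.
* Named graphs, JSON-LD and TriG are out of scope; so is SPARQL beyond
  SELECT + BGP.
* The registry's persistence stores interpreted class definitions, not the
  original ontology documents, so re-loading does not re-fetch or re-check
  ontologies.
* One service, one operation: interface documents describing several
  operations are rejected as malformed rather than partially parsed.
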