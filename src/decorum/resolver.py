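"""Query-driven resolution: build the database by asking the question.

Answers SELECT queries over a single basic graph pattern by intercepting
each pattern's predicate, discovering registered services that *attach*
that predicate, invoking them on the candidate nodes accumulated so far,
and merging their outputs — with provenance — into a query-specific working
store.  The pattern is finally evaluated over that store by plain
conjunctive matching, so a query against nothing but a seed graph reduces
to ordinary BGP matching.

The supported query subset is deliberately small (SELECT + conjunctive BGP;
no OPTIONAL/FILTER/UNION, no DL reasoning during matching): the mechanism
of interest is the interception-and-invocation loop, which is independent
of the sophistication of the query engine around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import Graph, Literal, URIRef, Variable
from rdflib.namespace import RDF
from rdflib.plugins.sparql.algebra import translateQuery
from rdflib.plugins.sparql.parser import parseQuery

from .client import Transport, invoke
from .errors import UnsupportedFeatureError
from .owl_model import satisfies
from .registry import Registry, RegistryRecord
from .rdf_core import graph_union

log = logging.getLogger(__name__)

PatternTerm = Union[Variable, URIRef, Literal]


@dataclass(frozen=True)
class TriplePattern:
    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def terms(self):
        return (self.subject, self.predicate, self.object)

    def variables(self) -> set[Variable]:
        return {t for t in self.terms() if isinstance(t, Variable)}


@dataclass
class QueryPlan:
    ordered_patterns: list[TriplePattern]
    #: pattern index (into ordered_patterns) → discovered services
    bindings: dict[int, list[RegistryRecord]] = field(default_factory=dict)
    #: patterns with a bound predicate served by nothing and absent from the seed
    unservable: list[TriplePattern] = field(default_factory=list)


@dataclass
class WorkingStore:
    """The dynamically generated, query-specific triplestore."""

    graph: Graph = field(default_factory=Graph)
    #: triple → service endpoint IRI, or "seed"
    provenance: dict[tuple, str] = field(default_factory=dict)

    def add(self, triple: tuple, source: str):
        if triple not in self.graph:
            self.graph.add(triple)
            self.provenance[triple] = source


@dataclass
class ResolveLimits:
    max_invocations: int = 50
    max_inputs_per_call: int = 100


@dataclass
class ResolveResult:
    solutions: list[dict[Variable, PatternTerm]]
    store: WorkingStore
    failures: list[str] = field(default_factory=list)
    exhausted: bool = False


_ALLOWED_ALGEBRA = {"SelectQuery", "Project", "BGP", "ToMultiSet"}


def parse_query(text: str) -> tuple[list[Variable], list[TriplePattern]]:
    """Parse a SELECT query over one basic graph pattern.

    Prefixed names are expanded; patterns come back in textual order.
    Any feature beyond the subset (OPTIONAL, FILTER, UNION, …) raises
    :class:`UnsupportedFeatureError`.
    """
    try:
        parsed = translateQuery(parseQuery(text))
    except UnsupportedFeatureError:
        raise
    except Exception as exc:
        raise UnsupportedFeatureError(f"query does not parse: {exc}") from exc
    algebra = parsed.algebra
    if algebra.name != "SelectQuery":
        raise UnsupportedFeatureError(
            f"only SELECT queries are supported, got {algebra.name}"
        )
    select_vars = list(algebra.PV)
    node = algebra
    while hasattr(node, "p") and node.p is not None:
        if node.name not in _ALLOWED_ALGEBRA:
            raise UnsupportedFeatureError(
                f"unsupported query feature: {node.name}"
            )
        node = node.p
    if node.name != "BGP":
        raise UnsupportedFeatureError(f"unsupported query feature: {node.name}")
    patterns = [TriplePattern(s, p, o) for s, p, o in node.triples]
    return select_vars, patterns


def plan(patterns: list[TriplePattern], reg: Registry) -> QueryPlan:
    """Order patterns so subjects are groundable before they are serviced.

    A subject is groundable when it is a concrete term or its variable has
    appeared in an already-planned pattern (seed data makes the first
    concrete-subject or free pattern a valid start).  Within those
    constraints, textual order is preserved, so the plan is deterministic.
    """
    bindings_by_pattern = [
        reg.find_by_property(p.predicate) if isinstance(p.predicate, URIRef) else []
        for p in patterns
    ]
    remaining = list(range(len(patterns)))
    ordered: list[int] = []
    grounded: set[Variable] = set()
    while remaining:
        pick = None
        for idx in remaining:
            subj = patterns[idx].subject
            if not isinstance(subj, Variable) or subj in grounded:
                pick = idx
                break
        if pick is None:  # no groundable subject: fall back to textual order
            pick = remaining[0]
        remaining.remove(pick)
        ordered.append(pick)
        grounded |= patterns[pick].variables()
    out = QueryPlan(ordered_patterns=[patterns[i] for i in ordered])
    for pos, idx in enumerate(ordered):
        if bindings_by_pattern[idx]:
            out.bindings[pos] = bindings_by_pattern[idx]
    return out


def match_bgp(g: Graph, patterns: list[TriplePattern]) -> list[dict]:
    """Conjunctive matching of a BGP over a plain graph, deterministic order."""
    solutions: list[dict] = [{}]
    for pat in patterns:
        extended = []
        for binding in solutions:
            query = tuple(
                binding.get(t) if isinstance(t, Variable) else t
                for t in pat.terms()
            )
            for triple in g.triples(query):
                new = dict(binding)
                consistent = True
                for term, value in zip(pat.terms(), triple):
                    if isinstance(term, Variable):
                        if term in new and new[term] != value:
                            consistent = False
                            break
                        new[term] = value
                if consistent:
                    extended.append(new)
        solutions = extended
    unique = {tuple(sorted((str(k), str(v)) for k, v in s.items())): s
              for s in solutions}
    return [unique[k] for k in sorted(unique)]


def _candidate_inputs(store: WorkingStore, record: RegistryRecord,
                      use_satisfies: bool = True) -> list[URIRef]:
    """Nodes in the store that can feed ``record``: explicitly typed with its
    input class, or structurally classifying into it."""
    g = store.graph
    cands = {
        s for s in g.subjects(RDF.type, record.description.input_class)
        if isinstance(s, URIRef)
    }
    if use_satisfies:
        nodes = {t for triple in g for t in (triple[0], triple[2])
                 if isinstance(t, URIRef)}
        for node in nodes - cands:
            try:
                ok, _ = satisfies(g, node, record.input_def, record.ontology)
            except Exception:
                continue
            if ok:
                cands.add(node)
    return sorted(cands, key=str)


def resolve(
    query: str,
    reg: Registry,
    seed: Graph,
    transport: Transport,
    limits: Optional[ResolveLimits] = None,
    poll_policy=None,
) -> ResolveResult:
    """Answer ``query`` by dynamically generating the store it needs.

    Walks the plan in order; for every pattern with discovered services,
    invokes each service (multiplexed over all current candidate inputs,
    each ``(service, node)`` pair at most once) and merges the outputs into
    the working store with provenance.  Invocation failures are recorded and
    resolution continues; exhausting ``limits`` flags the result partial.
    Finally the BGP is evaluated over the store.
    """
    limits = limits or ResolveLimits()
    select_vars, patterns = parse_query(query)
    query_plan = plan(patterns, reg)
    store = WorkingStore()
    for t in seed:
        store.add(t, "seed")
    invoked: set[tuple[str, URIRef]] = set()
    failures: list[str] = []
    exhausted = False
    n_invocations = 0
    for pos, pattern in enumerate(query_plan.ordered_patterns):
        if isinstance(pattern.predicate, URIRef) and pos not in query_plan.bindings:
            if next(store.graph.triples((None, pattern.predicate, None)), None) is None:
                query_plan.unservable.append(pattern)
            continue
        for record in query_plan.bindings.get(pos, []):
            endpoint = str(record.description.endpoint)
            cands = [
                c for c in _candidate_inputs(store, record)
                if (endpoint, c) not in invoked
            ]
            if isinstance(pattern.subject, URIRef):
                cands = [c for c in cands if c == pattern.subject] or cands
            while cands:
                if n_invocations >= limits.max_invocations:
                    exhausted = True
                    break
                batch, cands = (cands[: limits.max_inputs_per_call],
                                cands[limits.max_inputs_per_call:])
                message = graph_union(store.graph)
                for c in batch:
                    # re-classification: the service locates roots by type
                    message.add((c, RDF.type, record.description.input_class))
                invoked.update((endpoint, c) for c in batch)
                n_invocations += 1
                try:
                    result = invoke(
                        record.description.endpoint, message, transport,
                        poll_policy=poll_policy,
                    )
                except Exception as exc:
                    failures.append(f"{endpoint}: {exc}")
                    continue
                for root, msg in result.failures.items():
                    failures.append(f"{endpoint} on {root}: {msg}")
                for t in result.merged:
                    store.add(t, endpoint)
            if exhausted:
                break
        if exhausted:
            break
    solutions = [
        {v: s[v] for v in select_vars if v in s}
        for s in match_bgp(store.graph, patterns)
    ]
    unique = {tuple(sorted((str(k), str(v)) for k, v in s.items())): s
              for s in solutions}
    solutions = [unique[k] for k in sorted(unique)]
    return ResolveResult(solutions, store, failures, exhausted)
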