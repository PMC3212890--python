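"""Synthetic fixture generators.

Three generators, all reproducible from a seed:

* :func:`build_chain` — a linear composition of services where each
  service's attached (object) property produces the typed input of the
  next, mirroring the pathway → participant gene → encoded protein style of
  composition; the generator knows the closed-form answer of the
  end-to-end query.
* :func:`build_random_catalogue` — random service families over a shared
  property pool, for registry index-consistency checks.
* :func:`generate_matchmaking_cases` — labeled (graph, class) membership
  cases spanning every supported restriction kind, balanced between
  positives and negatives, for checker-vs-oracle agreement suites.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdflib import Graph, Literal, Namespace, URIRef, Variable
from rdflib.namespace import OWL, RDF, RDFS, XSD

from ..description import ServiceDescription
from ..host import ServiceImplementation
from ..owl_model import (ClassDefinition, Ontology, PropertyRestriction,
                         RestrictionKind)
from .catalogue import FixtureCatalogue, _restriction

CHAIN_ONT_DOC = "http://example.org/chain/ontology.owl"
CHAIN = Namespace(CHAIN_ONT_DOC + "#")


@dataclass(frozen=True)
class SyntheticSpec:
    n_services: int = 6
    property_pool_size: int = 8
    restriction_depth: int = 2  # fillers may be classes with own restrictions
    chain_length: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.restriction_depth <= 2):
            raise ValueError("restriction_depth must be 1 or 2")


# -- service chains --------------------------------------------------------


@dataclass
class ChainFixture:
    catalogue: FixtureCatalogue
    seed_graph: Graph
    seed_root: URIRef
    query: str
    #: the single expected solution, variable name → term
    expected: dict[Variable, object]
    length: int


def _chain_ontology(length: int) -> Graph:
    g = Graph()
    g.bind("chain", CHAIN)
    for i in range(1, length + 2):
        stage = CHAIN[f"Stage{i}"]
        g.add((stage, RDF.type, OWL.Class))
        g.add((stage, RDFS.subClassOf,
               _restriction(g, CHAIN[f"label{i}"], OWL.minCardinality,
                            Literal(1, datatype=XSD.nonNegativeInteger))))
        g.add((CHAIN[f"label{i}"], RDF.type, OWL.DatatypeProperty))
    for i in range(1, length + 1):
        out_cls = CHAIN[f"Linked{i}"]
        g.add((out_cls, RDF.type, OWL.Class))
        g.add((out_cls, RDFS.subClassOf, CHAIN[f"Stage{i}"]))
        g.add((out_cls, RDFS.subClassOf,
               _restriction(g, CHAIN[f"link{i}"], OWL.someValuesFrom,
                            CHAIN[f"Stage{i + 1}"])))
        g.add((CHAIN[f"link{i}"], RDF.type, OWL.ObjectProperty))
    return g


def _label_for(node: URIRef, stage: int) -> Literal:
    return Literal(f"{node}#label{stage}")


def build_chain(spec: SyntheticSpec) -> ChainFixture:
    """A deterministic service chain of ``spec.chain_length`` >= 2 steps.

    Service ``i`` consumes ``Stage_i`` individuals (required: ``label_i``)
    and attaches ``link_i`` pointing at a fresh ``Stage_{i+1}`` individual
    whose IRI and label are pure functions of the input root — so the
    end-to-end query has exactly one, precomputable solution.
    """
    k = spec.chain_length
    if k < 2:
        raise ValueError("chain_length must be >= 2")
    cat = FixtureCatalogue()
    cat.ontologies[CHAIN_ONT_DOC] = _chain_ontology(k)
    for i in range(1, k + 1):
        endpoint = URIRef(f"http://example.org/chain/{spec.seed}/service{i}")
        desc = ServiceDescription(
            name=f"ChainStep{i}",
            endpoint=endpoint,
            input_class=CHAIN[f"Stage{i}"],
            output_class=CHAIN[f"Linked{i}"],
            description_text=f"Links a Stage{i} individual to its Stage{i + 1}.",
            authority="example.org",
        )

        def annotate(g, root, params, i=i):
            nxt = URIRef(f"{root}/s{i}")
            return [
                (root, CHAIN[f"link{i}"], nxt),
                (nxt, RDF.type, CHAIN[f"Stage{i + 1}"]),
                (nxt, CHAIN[f"label{i + 1}"], _label_for(nxt, i + 1)),
            ]

        cat.add_service(f"chain{i}", ServiceImplementation(desc, annotate, "sync"))

    root = URIRef(f"http://example.org/chain/{spec.seed}/data/seed")
    seed_graph = Graph()
    seed_graph.add((root, RDF.type, CHAIN.Stage1))
    seed_graph.add((root, CHAIN.label1, _label_for(root, 1)))

    patterns = [f"<{root}> chain:link1 ?v1 ."]
    for i in range(2, k + 1):
        patterns.append(f"?v{i - 1} chain:link{i} ?v{i} .")
    patterns.append(f"?v{k} chain:label{k + 1} ?lab .")
    query = (
        f"PREFIX chain: <{CHAIN}>\n"
        f"SELECT {' '.join(f'?v{i}' for i in range(1, k + 1))} ?lab\n"
        f"WHERE {{ {' '.join(patterns)} }}"
    )

    expected: dict[Variable, object] = {}
    node = root
    for i in range(1, k + 1):
        node = URIRef(f"{node}/s{i}")
        expected[Variable(f"v{i}")] = node
    expected[Variable("lab")] = _label_for(node, k + 1)
    return ChainFixture(cat, seed_graph, root, query, expected, k)


# -- random catalogues -----------------------------------------------------

RANDNS = Namespace("http://example.org/random.owl#")


def build_random_catalogue(spec: SyntheticSpec) -> FixtureCatalogue:
    """Random services over a shared property pool (for index invariants).

    Each service requires 0–2 pool properties and attaches 1–3 others; the
    attached values are strings, so any catalogue member can be invoked on
    any node that meets its requirements.
    """
    rng = random.Random(spec.seed)
    pool = [RANDNS[f"p{i}"] for i in range(spec.property_pool_size)]
    cat = FixtureCatalogue()
    doc = Graph()
    doc.bind("rnd", RANDNS)
    for p in pool:
        doc.add((p, RDF.type, OWL.DatatypeProperty))
    for j in range(spec.n_services):
        required = rng.sample(pool, rng.randint(0, min(2, len(pool) - 1)))
        attachable = [p for p in pool if p not in required]
        attached = rng.sample(attachable, rng.randint(1, min(3, len(attachable))))
        in_cls, out_cls = RANDNS[f"In{spec.seed}_{j}"], RANDNS[f"Out{spec.seed}_{j}"]
        doc.add((in_cls, RDF.type, OWL.Class))
        for p in required:
            doc.add((in_cls, RDFS.subClassOf,
                     _restriction(doc, p, OWL.minCardinality,
                                  Literal(1, datatype=XSD.nonNegativeInteger))))
        doc.add((out_cls, RDF.type, OWL.Class))
        doc.add((out_cls, RDFS.subClassOf, in_cls))
        for p in attached:
            doc.add((out_cls, RDFS.subClassOf,
                     _restriction(doc, p, OWL.someValuesFrom, XSD.string)))
        endpoint = URIRef(f"http://example.org/random/{spec.seed}/service{j}")
        desc = ServiceDescription(
            name=f"Random{spec.seed}_{j}",
            endpoint=endpoint,
            input_class=in_cls,
            output_class=out_cls,
            authority="example.org",
        )

        def annotate(g, root, params, attached=tuple(attached), j=j):
            return [(root, p, Literal(f"svc{j}")) for p in attached]

        cat.add_service(f"random{j}", ServiceImplementation(desc, annotate, "sync"))
    cat.ontologies["http://example.org/random.owl"] = doc
    return cat


# -- matchmaking corpora ---------------------------------------------------

MATCH = Namespace("http://example.org/match.owl#")


@dataclass
class MatchCase:
    graph: Graph
    cls: ClassDefinition
    ontology: Ontology
    expected: bool
    node: URIRef = MATCH.node


def _helper_class(idx: int, prop: URIRef) -> ClassDefinition:
    iri = MATCH[f"Helper{idx}"]
    return ClassDefinition(
        iri,
        (PropertyRestriction(prop, RestrictionKind.MIN_CARDINALITY, None, 1),),
    )


def generate_matchmaking_cases(spec: SyntheticSpec, n_cases: int = 1000) -> list[MatchCase]:
    """Labeled structural-membership cases across all restriction kinds.

    Positives are built to satisfy every restriction; negatives satisfy all
    but one, broken in a kind-appropriate way (missing witness, wrong
    datatype, short cardinality, absent required value, offending
    allValuesFrom member).  Positive/negative balance is ~50%.
    """
    rng = random.Random(spec.seed)
    pool = [MATCH[f"q{i}"] for i in range(max(spec.property_pool_size, 4))]
    noise_pool = [MATCH[f"noise{i}"] for i in range(4)]
    kinds = list(RestrictionKind)
    cases: list[MatchCase] = []
    for case_idx in range(n_cases):
        n_restrictions = rng.randint(1, 3)
        props = rng.sample(pool, n_restrictions)
        restrictions = []
        helpers: dict[URIRef, ClassDefinition] = {}
        for ridx, prop in enumerate(props):
            kind = rng.choice(kinds)
            if kind is RestrictionKind.MIN_CARDINALITY:
                restrictions.append(PropertyRestriction(
                    prop, kind, None, rng.randint(1, 3)))
            elif kind is RestrictionKind.HAS_VALUE:
                needed = (
                    Literal(f"v{rng.randint(0, 5)}")
                    if rng.random() < 0.5
                    else MATCH[f"ind{rng.randint(0, 5)}"]
                )
                restrictions.append(PropertyRestriction(prop, kind, needed))
            else:
                if spec.restriction_depth >= 2 and rng.random() < 0.4:
                    helper_prop = rng.choice(pool)
                    helper = _helper_class(f"{case_idx}_{ridx}", helper_prop)
                    helpers[helper.iri] = helper
                    filler = helper.iri
                else:
                    filler = XSD.string
                restrictions.append(PropertyRestriction(prop, kind, filler))
        cls = ClassDefinition(MATCH[f"Case{case_idx}"], tuple(restrictions))
        ont = Ontology(classes={cls.iri: cls, **helpers})

        expected = rng.random() < 0.5
        broken = None if expected else rng.choice(restrictions)
        g = Graph()
        node = MATCH.node
        for r in restrictions:
            _populate(g, node, r, ont, rng, break_it=(r is broken))
        for _ in range(rng.randint(0, 2)):  # noise on unrestricted properties
            g.add((node, rng.choice(noise_pool), Literal(rng.randint(0, 99))))
        cases.append(MatchCase(g, cls, ont, expected))
    return cases


def _conforming_value(g, filler, ont, rng, tag):
    """A term that is a member of ``filler`` (datatype or helper class)."""
    if filler == XSD.string:
        return Literal(f"s{tag}")
    helper = ont.classes[filler]
    value = MATCH[f"w{tag}"]
    if rng.random() < 0.5:
        g.add((value, RDF.type, filler))  # explicit typing route
    else:  # structural route: satisfy the helper's requirement
        g.add((value, helper.restrictions[0].property, Literal(f"h{tag}")))
    return value


def _violating_value(g, filler, rng, tag):
    """A term that is definitely not a member of ``filler``."""
    if filler == XSD.string:
        return Literal(rng.randint(0, 9))  # xsd:integer literal
    return MATCH[f"bad{tag}"]  # bare node: untyped, no helper property


def _populate(g, node, r: PropertyRestriction, ont, rng, break_it: bool):
    tag = rng.randint(0, 10 ** 6)
    if r.kind is RestrictionKind.MIN_CARDINALITY:
        count = r.min_count - 1 if break_it else r.min_count + rng.randint(0, 1)
        for i in range(count):
            g.add((node, r.property, Literal(f"c{tag}_{i}")))
    elif r.kind is RestrictionKind.HAS_VALUE:
        if break_it:
            g.add((node, r.property, Literal(f"other{tag}")))
        else:
            g.add((node, r.property, r.filler))
            if rng.random() < 0.3:
                g.add((node, r.property, Literal(f"extra{tag}")))
    elif r.kind is RestrictionKind.SOME_VALUES_FROM:
        if break_it:
            # only non-members (possibly none at all)
            for _ in range(rng.randint(0, 2)):
                g.add((node, r.property, _violating_value(g, r.filler, rng, tag)))
                tag += 1
        else:
            g.add((node, r.property,
                   _conforming_value(g, r.filler, ont, rng, tag)))
    elif r.kind is RestrictionKind.ALL_VALUES_FROM:
        if break_it:
            g.add((node, r.property, _violating_value(g, r.filler, rng, tag)))
            if rng.random() < 0.5:
                g.add((node, r.property,
                       _conforming_value(g, r.filler, ont, rng, tag + 1)))
        else:
            # zero values is vacuously fine
            for i in range(rng.randint(0, 2)):
                g.add((node, r.property,
                       _conforming_value(g, r.filler, ont, rng, tag + i)))
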