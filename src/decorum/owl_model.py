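"""OWL class model and structural matchmaking.

A service's interface is a pair of OWL classes whose property restrictions
say what data the service needs and what it will add.  Matchmaking here is
*structural*: an individual belongs to a class when its asserted triples
satisfy every restriction of the class (and, recursively, of its named
superclasses).  No description-logic entailment is performed — the point of
the pattern is that providers and clients work without a reasoner — but the
checking function is the single hook point where a full reasoner could be
substituted.

Supported OWL subset: ``owl:Restriction`` with ``someValuesFrom`` /
``allValuesFrom`` / ``minCardinality`` / ``hasValue``, ``owl:intersectionOf``,
and ``rdfs:subClassOf`` to named classes, reached through either
``rdfs:subClassOf`` or ``owl:equivalentClass``.  Anything else
(``unionOf``, ``complementOf``, max cardinalities …) produces a load-time
warning and is excluded from matchmaking, never silently dropped.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import MissingClassError, OntologyError
from .rdf_core import Fetcher, parse_graph
from .vocab import MEDIA_RDFXML

log = logging.getLogger(__name__)


class RestrictionKind(enum.Enum):
    SOME_VALUES_FROM = "someValuesFrom"
    ALL_VALUES_FROM = "allValuesFrom"
    MIN_CARDINALITY = "minCardinality"
    HAS_VALUE = "hasValue"


Filler = Union[URIRef, Literal, None]


@dataclass(frozen=True)
class PropertyRestriction:
    """One ``owl:Restriction`` on a property.

    ``filler`` is the value class/datatype (someValuesFrom, allValuesFrom)
    or the required term (hasValue); ``min_count`` applies to
    minCardinality only and counts *distinct RDF terms*.
    """

    property: URIRef
    kind: RestrictionKind
    filler: Filler = None
    min_count: int = 1

    def __post_init__(self):
        needs_filler = self.kind in (
            RestrictionKind.SOME_VALUES_FROM,
            RestrictionKind.ALL_VALUES_FROM,
            RestrictionKind.HAS_VALUE,
        )
        if needs_filler and self.filler is None:
            raise ValueError(f"{self.kind.value} restriction requires a filler")
        if not needs_filler and self.filler is not None:
            raise ValueError(f"{self.kind.value} restriction takes no filler")
        if self.kind is RestrictionKind.MIN_CARDINALITY and self.min_count < 1:
            raise ValueError("minCardinality must be >= 1")


@dataclass(frozen=True)
class ClassDefinition:
    """A named OWL class as a flat list of restrictions plus named superclasses."""

    iri: URIRef
    restrictions: tuple[PropertyRestriction, ...] = ()
    named_superclasses: frozenset[URIRef] = frozenset()


@dataclass
class Ontology:
    """Class definitions plus the set of declared datatype properties."""

    classes: dict[URIRef, ClassDefinition] = field(default_factory=dict)
    datatype_properties: set[URIRef] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "Ontology") -> "Ontology":
        merged = Ontology(dict(self.classes), set(self.datatype_properties),
                          list(self.warnings))
        merged.classes.update(other.classes)
        merged.datatype_properties |= other.datatype_properties
        merged.warnings += other.warnings
        return merged


_UNSUPPORTED = (OWL.unionOf, OWL.complementOf, OWL.maxCardinality,
                OWL.cardinality, OWL.oneOf)


def _parse_restriction(g: Graph, node, warnings: list[str]) -> Optional[PropertyRestriction]:
    prop = g.value(node, OWL.onProperty)
    if not isinstance(prop, URIRef):
        warnings.append(f"restriction without a named onProperty: {node}")
        return None
    for pred in _UNSUPPORTED:
        if g.value(node, pred) is not None:
            warnings.append(
                f"unsupported construct {pred} on restriction of {prop}; excluded"
            )
            return None
    some = g.value(node, OWL.someValuesFrom)
    if some is not None:
        return PropertyRestriction(prop, RestrictionKind.SOME_VALUES_FROM, some)
    allv = g.value(node, OWL.allValuesFrom)
    if allv is not None:
        return PropertyRestriction(prop, RestrictionKind.ALL_VALUES_FROM, allv)
    hasv = g.value(node, OWL.hasValue)
    if hasv is not None:
        return PropertyRestriction(prop, RestrictionKind.HAS_VALUE, hasv)
    minc = g.value(node, OWL.minCardinality)
    if minc is None:
        minc = g.value(node, OWL.minQualifiedCardinality)
    if minc is not None:
        return PropertyRestriction(
            prop, RestrictionKind.MIN_CARDINALITY, None, int(minc.toPython())
        )
    warnings.append(f"restriction on {prop} carries no supported facet; excluded")
    return None


def _collect(g: Graph, expr, restrictions: list, supers: set, warnings: list[str]):
    """Flatten a class expression into restrictions + named superclasses."""
    if isinstance(expr, URIRef):
        supers.add(expr)
        return
    if (expr, RDF.type, OWL.Restriction) in g or g.value(expr, OWL.onProperty):
        r = _parse_restriction(g, expr, warnings)
        if r is not None:
            restrictions.append(r)
        return
    members = g.value(expr, OWL.intersectionOf)
    if members is not None:
        for member in Collection(g, members):
            _collect(g, member, restrictions, supers, warnings)
        return
    for pred in _UNSUPPORTED:
        if g.value(expr, pred) is not None:
            warnings.append(f"unsupported class expression {pred}; excluded")
            return
    warnings.append(f"unrecognised class expression {expr}; excluded")


def ontology_from_graph(g: Graph) -> Ontology:
    """Interpret an already-parsed OWL document."""
    ont = Ontology()
    named = [c for c in g.subjects(RDF.type, OWL.Class) if isinstance(c, URIRef)]
    for cls in sorted(set(named), key=str):
        restrictions: list[PropertyRestriction] = []
        supers: set[URIRef] = set()
        for expr in list(g.objects(cls, RDFS.subClassOf)) + list(
            g.objects(cls, OWL.equivalentClass)
        ):
            _collect(g, expr, restrictions, supers, ont.warnings)
        supers.discard(OWL.Thing)
        ont.classes[cls] = ClassDefinition(
            cls, tuple(restrictions), frozenset(supers)
        )
    for p in g.subjects(RDF.type, OWL.DatatypeProperty):
        if isinstance(p, URIRef):
            ont.datatype_properties.add(p)
    for msg in ont.warnings:
        log.warning("%s", msg)
    return ont


def load_ontology(
    source: Union[bytes, str, URIRef],
    fetch: Optional[Fetcher] = None,
    media_type: str = MEDIA_RDFXML,
) -> Ontology:
    """Load an ontology from document bytes or by dereferencing its IRI.

    Class IRIs must resolve to an OWL document; an IRI source without a
    working fetcher, or a fetch failure, is an :class:`OntologyError`
    naming the IRI.
    """
    if isinstance(source, bytes):
        return ontology_from_graph(parse_graph(source, media_type))
    iri = str(source)
    if fetch is None:
        raise OntologyError(f"no fetcher available to resolve ontology {iri}")
    try:
        payload, mt = fetch(iri)
    except Exception as exc:
        raise OntologyError(f"could not resolve ontology {iri}: {exc}") from exc
    return ontology_from_graph(parse_graph(payload, mt))


_XSD_NS = str(XSD)


def is_datatype_filler(filler: URIRef) -> bool:
    return str(filler).startswith(_XSD_NS) or filler == RDFS.Literal


def _literal_matches(value, datatype: URIRef) -> bool:
    if not isinstance(value, Literal):
        return False
    if datatype == RDFS.Literal:
        return True
    dt = value.datatype or XSD.string  # a plain literal counts as a string
    return dt == datatype


def all_restrictions(
    cls: ClassDefinition, ont: Ontology
) -> list[PropertyRestriction]:
    """Restrictions of ``cls`` plus those inherited from named superclasses.

    Superclasses not defined in the ontology (external vocabulary) contribute
    nothing; cycles in the superclass graph are tolerated.
    """
    out: list[PropertyRestriction] = []
    seen: set[URIRef] = set()
    stack = [cls]
    while stack:
        c = stack.pop()
        if c.iri in seen:
            continue
        seen.add(c.iri)
        out.extend(c.restrictions)
        for sup in sorted(c.named_superclasses, key=str):
            if sup in ont.classes:
                stack.append(ont.classes[sup])
    return out


def _value_in_class(g, value, filler: URIRef, ont: Ontology, active) -> bool:
    if is_datatype_filler(filler):
        return _literal_matches(value, filler)
    if isinstance(value, Literal):
        return False
    if (value, RDF.type, filler) in g:
        return True
    if filler not in ont.classes:
        raise MissingClassError(
            f"restriction filler {filler} is not defined in the ontology"
        )
    ok, _ = _satisfies(g, value, ont.classes[filler], ont, active)
    return ok


def _restriction_met(g, node, r: PropertyRestriction, ont, active) -> bool:
    values = list(g.objects(node, r.property))
    if r.kind is RestrictionKind.MIN_CARDINALITY:
        return len(set(values)) >= r.min_count
    if r.kind is RestrictionKind.HAS_VALUE:
        return r.filler in values
    if r.kind is RestrictionKind.SOME_VALUES_FROM:
        return any(_value_in_class(g, v, r.filler, ont, active) for v in values)
    # allValuesFrom: vacuously true when the property is absent
    return all(_value_in_class(g, v, r.filler, ont, active) for v in values)


def _satisfies(g, node, cls, ont, active) -> tuple[bool, list[PropertyRestriction]]:
    key = (node, cls.iri)
    if key in active:
        # cyclic structural dependency: cannot be established from the data
        return False, list(all_restrictions(cls, ont))
    active = active | {key}
    unmet = [
        r for r in all_restrictions(cls, ont)
        if not _restriction_met(g, node, r, ont, active)
    ]
    return not unmet, unmet


def satisfies(
    g: Graph,
    node: Union[URIRef, BNode],
    cls: ClassDefinition,
    ont: Ontology,
) -> tuple[bool, list[PropertyRestriction]]:
    """Structurally classify ``node`` against ``cls``.

    Returns ``(ok, unmet)`` where ``unmet`` lists every failed restriction.
    A ``someValuesFrom`` over a named class accepts a value that is either
    explicitly typed with that class or itself structurally satisfies it.
    Explicit ``rdf:type cls.iri`` on the node is *not* consulted: typing is a
    root-location mechanism, membership is decided by the restrictions.
    A restriction filler naming a class absent from ``ont`` raises
    :class:`MissingClassError` rather than silently passing.
    """
    return _satisfies(g, node, cls, ont, frozenset())


def attached_properties(
    input_cls: ClassDefinition,
    output_cls: ClassDefinition,
    ont: Ontology,
) -> set[URIRef]:
    """Properties restricted by the output class but not by the input class.

    This set is the semantic signature of what a service computes — the
    predicates it will attach to its input — and is what a registry indexes
    for discovery.  Inherited (named-superclass) restrictions count on both
    sides.
    """
    out_props = {r.property for r in all_restrictions(output_cls, ont)}
    in_props = {r.property for r in all_restrictions(input_cls, ont)}
    return out_props - in_props
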