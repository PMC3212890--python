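"""Independent brute-force membership checker.

A deliberately naive re-statement of structural classification, written
directly from the meaning of each restriction kind with explicit loops and
no shared code with :mod:`decorum.owl_model`.  It exists purely as the
second route in agreement tests: both checkers are run over generated
(graph, class) corpora and must never disagree.
"""

from __future__ import annotations

from rdflib import Literal
from rdflib.namespace import RDF, RDFS, XSD


def _gather_restrictions(cls, ont):
    """All restrictions of cls and of its defined named superclasses (BFS)."""
    queue = [cls.iri]
    visited = []
    collected = []
    while queue:
        iri = queue.pop(0)
        if iri in visited:
            continue
        visited.append(iri)
        definition = ont.classes.get(iri)
        if definition is None:
            continue
        for r in definition.restrictions:
            collected.append(r)
        for sup in definition.named_superclasses:
            queue.append(sup)
    return collected


def _literal_fits(value, datatype_iri):
    if not isinstance(value, Literal):
        return False
    if datatype_iri == RDFS.Literal:
        return True
    actual = value.datatype if value.datatype is not None else XSD.string
    return actual == datatype_iri


def _member_of(g, value, filler, ont, trail):
    if str(filler).startswith(str(XSD)) or filler == RDFS.Literal:
        return _literal_fits(value, filler)
    if isinstance(value, Literal):
        return False
    if (value, RDF.type, filler) in g:
        return True
    if (value, filler) in trail:
        return False
    definition = ont.classes.get(filler)
    if definition is None:
        raise KeyError(f"class {filler} not defined")
    return _check(g, value, definition, ont, trail + [(value, filler)])


def _check(g, node, cls, ont, trail):
    for r in _gather_restrictions(cls, ont):
        values = [o for s, p, o in g if s == node and p == r.property]
        kind = r.kind.value
        if kind == "minCardinality":
            distinct = []
            for v in values:
                if v not in distinct:
                    distinct.append(v)
            if len(distinct) < r.min_count:
                return False
        elif kind == "hasValue":
            if not any(v == r.filler for v in values):
                return False
        elif kind == "someValuesFrom":
            witnesses = [
                v for v in values if _member_of(g, v, r.filler, ont, trail)
            ]
            if len(witnesses) == 0:
                return False
        elif kind == "allValuesFrom":
            offenders = [
                v for v in values if not _member_of(g, v, r.filler, ont, trail)
            ]
            if len(offenders) > 0:
                return False
        else:  # pragma: no cover - unreachable with the supported subset
            raise ValueError(f"unknown restriction kind {kind}")
    return True


def brute_force_satisfies(g, node, cls, ont) -> bool:
    """Does ``node`` structurally classify into ``cls``?  Naive reference."""
    return _check(g, node, cls, ont, [])
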