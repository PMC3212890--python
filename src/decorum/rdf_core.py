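"""Graph substrate.

Thin, opinionated layer over :mod:`rdflib`: two wire dialects (RDF/XML and
N3), explicit typed-root extraction, graph isomorphism as the equality
relation for responses, and pass-by-reference resolution via
``rdfs:isDefinedBy``.

Service input and output roots must be URI-named: the whole pattern rests on
the root's IRI being preserved by the service, and a blank node has no IRI to
preserve.  Blank nodes typed with the class of interest are therefore
diagnosed, never returned.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Tuple, Union

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import RDF, RDFS

from .errors import GraphParseError, UnsupportedMediaTypeError
from .vocab import MEDIA_N3, MEDIA_RDFXML

log = logging.getLogger(__name__)

#: A fetcher maps an IRI to a retrievable RDF document: ``(payload, media_type)``.
Fetcher = Callable[[str], Tuple[bytes, str]]

Term = Union[URIRef, BNode, Literal]

_PARSE_FORMAT = {MEDIA_RDFXML: "xml", MEDIA_N3: "n3"}
_SERIALIZE_FORMAT = {MEDIA_RDFXML: "xml", MEDIA_N3: "n3"}

MEDIA_TYPES = (MEDIA_RDFXML, MEDIA_N3)


def _dialect(media_type: str, table: dict) -> str:
    base = media_type.split(";")[0].strip().lower()
    try:
        return table[base]
    except KeyError:
        raise UnsupportedMediaTypeError(
            f"unsupported RDF media type {media_type!r}; "
            f"expected one of {sorted(table)}"
        ) from None


def parse_graph(payload: bytes, media_type: str) -> Graph:
    """Parse an RDF/XML or N3 payload into a graph.

    Unknown media types raise :class:`UnsupportedMediaTypeError`; payloads
    that fail to parse in a supported dialect raise :class:`GraphParseError`.
    """
    fmt = _dialect(media_type, _PARSE_FORMAT)
    g = Graph()
    try:
        g.parse(data=payload, format=fmt)
    except Exception as exc:  # rdflib raises dialect-specific errors
        raise GraphParseError(f"malformed {media_type} payload: {exc}") from exc
    return g


def serialize_graph(g: Graph, media_type: str) -> bytes:
    """Serialize ``g`` in the requested dialect; round-trips up to isomorphism."""
    fmt = _dialect(media_type, _SERIALIZE_FORMAT)
    return g.serialize(format=fmt, encoding="utf-8")


def graphs_isomorphic(a: Graph, b: Graph) -> bool:
    """RDF graph equality: identical triples up to a bijection of blank nodes."""
    return isomorphic(a, b)


def graph_union(*graphs: Graph) -> Graph:
    out = Graph()
    for g in graphs:
        for t in g:
            out.add(t)
    return out


def extract_typed_roots(g: Graph, class_iri: URIRef) -> list[URIRef]:
    """Return URI-named subjects carrying ``rdf:type class_iri``.

    Order is lexicographic on the IRI string so callers see a deterministic
    sequence.  Blank-node subjects of the sought type are logged as a
    diagnostic and omitted.
    """
    roots: set[URIRef] = set()
    blanks: list[BNode] = []
    for s in g.subjects(RDF.type, class_iri):
        if isinstance(s, URIRef):
            roots.add(s)
        else:
            blanks.append(s)
    if blanks:
        log.warning(
            "ignoring %d blank-node individual(s) typed %s: service roots "
            "must be URI-named (%s)",
            len(blanks), class_iri, ", ".join(str(b) for b in blanks),
        )
    return sorted(roots, key=str)


def resolve_by_reference(
    g: Graph,
    node: URIRef,
    fetch: Fetcher,
    depth_limit: int = 1,
) -> Graph:
    """Merge documents referenced by ``(node, rdfs:isDefinedBy, url)`` into a copy of ``g``.

    The referenced documents are expected to supply the node's missing
    triples, so large data can travel by reference rather than inline.
    Dereferencing is repeated on ``node`` up to ``depth_limit`` rounds
    (documents may themselves add further references); each URL is fetched at
    most once, which also terminates reference cycles.  A failed fetch is a
    warning and the partial merge is returned.
    """
    if depth_limit < 0:
        raise ValueError("depth_limit must be >= 0")
    merged = graph_union(g)
    seen: set[str] = set()
    for _ in range(depth_limit):
        pending = [
            str(o)
            for o in merged.objects(node, RDFS.isDefinedBy)
            if isinstance(o, URIRef) and str(o) not in seen
        ]
        if not pending:
            break
        for url in sorted(pending):
            seen.add(url)
            try:
                payload, media_type = fetch(url)
                doc = parse_graph(payload, media_type)
            except Exception as exc:
                log.warning("could not resolve reference %s for %s: %s",
                            url, node, exc)
                continue
            for t in doc:
                merged.add(t)
    return merged


def triples_of(g: Graph) -> Iterable[tuple]:
    return iter(g)
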