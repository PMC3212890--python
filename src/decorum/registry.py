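"""Property-indexed service registry.

The registry's index key is the *attached property* set: the predicates a
service's output class restricts beyond its input class — i.e. what the
service computes.  Discovery then works in two directions:

* given a data node, which services can consume it
  (:meth:`Registry.find_by_input_instance`, structural classification by
  default so data from any ontological framework matches as long as it
  carries the required properties; an ``rdf:type``-only fast path is
  available);
* given a predicate, which services can attach it
  (:meth:`Registry.find_by_property`).

:meth:`Registry.property_menu` combines the two into the "menu of
relationships" a data-exploration client shows for a selected node.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, replace
from typing import Callable

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from .client import OntologyLoader, Transport, fetch_description
from .description import ServiceDescription, emit_description, parse_description
from .errors import (DescriptionError, GraphParseError, RegistrationError,
                     TransportError, UnsupportedMediaTypeError)
from .owl_model import (ClassDefinition, Ontology, PropertyRestriction,
                        RestrictionKind, attached_properties, satisfies)


@dataclass
class RegistryRecord:
    description: ServiceDescription
    input_def: ClassDefinition
    output_def: ClassDefinition
    ontology: Ontology
    attached: frozenset[URIRef]
    alive: bool = True
    last_checked: float = 0.0
    stale: bool = False  # description changed since registration


class Registry:
    """In-memory store with consistent by-class and by-property indexes."""

    def __init__(self):
        self._records: dict[str, RegistryRecord] = {}
        self._by_property: dict[URIRef, set[str]] = {}
        self._by_input_class: dict[URIRef, set[str]] = {}

    # -- registration ------------------------------------------------------

    def register(
        self,
        endpoint: URIRef,
        transport: Transport,
        ont_loader: OntologyLoader,
        clock: Callable[[], float] = time.time,
    ) -> RegistryRecord:
        """Fetch, validate and index the service at ``endpoint``.

        Both interface classes must resolve to definitions; otherwise
        registration is refused with a diagnostic.  Re-registering an
        endpoint replaces its record and reindexes consistently.
        """
        try:
            desc = fetch_description(endpoint, transport)
        except (TransportError, GraphParseError, DescriptionError,
                UnsupportedMediaTypeError) as exc:
            raise RegistrationError(
                f"cannot register {endpoint}: {exc}"
            ) from exc
        ont = Ontology()
        for cls_iri in (desc.input_class, desc.output_class):
            try:
                ont = ont.merge(ont_loader(cls_iri))
            except Exception as exc:
                raise RegistrationError(
                    f"cannot register {endpoint}: ontology for {cls_iri} "
                    f"unresolvable ({exc})"
                ) from exc
        missing = [c for c in (desc.input_class, desc.output_class)
                   if c not in ont.classes]
        if missing:
            raise RegistrationError(
                f"cannot register {endpoint}: class(es) not defined by their "
                f"ontology: {', '.join(map(str, missing))}"
            )
        input_def = ont.classes[desc.input_class]
        output_def = ont.classes[desc.output_class]
        record = RegistryRecord(
            description=desc,
            input_def=input_def,
            output_def=output_def,
            ontology=ont,
            attached=frozenset(attached_properties(input_def, output_def, ont)),
            alive=True,
            last_checked=clock(),
        )
        self._store(record)
        return record

    def _store(self, record: RegistryRecord):
        key = str(record.description.endpoint)
        if key in self._records:
            self._unindex(key)
        self._records[key] = record
        self._by_input_class.setdefault(record.description.input_class, set()).add(key)
        for p in record.attached:
            self._by_property.setdefault(p, set()).add(key)

    def _unindex(self, key: str):
        old = self._records.pop(key)
        self._by_input_class.get(old.description.input_class, set()).discard(key)
        for p in old.attached:
            self._by_property.get(p, set()).discard(key)

    # -- discovery ---------------------------------------------------------

    @property
    def records(self) -> list[RegistryRecord]:
        return [self._records[k] for k in sorted(self._records)]

    def _live(self, keys, include_dead: bool) -> list[RegistryRecord]:
        return [
            self._records[k]
            for k in sorted(keys)
            if include_dead or self._records[k].alive
        ]

    def find_by_property(
        self, predicate: URIRef, include_dead: bool = False
    ) -> list[RegistryRecord]:
        """Services able to attach ``predicate`` to their input."""
        return self._live(self._by_property.get(predicate, ()), include_dead)

    def find_by_input_instance(
        self,
        g: Graph,
        node: URIRef,
        by_type_only: bool = False,
        include_dead: bool = False,
    ) -> list[RegistryRecord]:
        """Services whose input class the node classifies into.

        Default is the full structural check, so untyped (or foreign-typed)
        data still matches when it carries the required properties;
        ``by_type_only`` restricts to services whose input class the node is
        explicitly ``rdf:type``-ed with.
        """
        if by_type_only:
            keys = set()
            for cls in g.objects(node, RDF.type):
                keys |= self._by_input_class.get(cls, set())
            return self._live(keys, include_dead)
        hits = []
        for record in self._live(self._records, include_dead):
            ok, _ = satisfies(g, node, record.input_def, record.ontology)
            if ok:
                hits.append(record)
        return hits

    def property_menu(
        self, g: Graph, node: URIRef, by_type_only: bool = False
    ) -> dict[URIRef, list[RegistryRecord]]:
        """The discovery menu for a node: attachable predicate → services.

        Every attached property of every service that can consume the node
        appears as a key.
        """
        menu: dict[URIRef, list[RegistryRecord]] = {}
        for record in self.find_by_input_instance(g, node, by_type_only):
            for p in sorted(record.attached, key=str):
                menu.setdefault(p, []).append(record)
        return menu

    # -- liveness ----------------------------------------------------------

    def check_alive(
        self,
        endpoint: URIRef,
        transport: Transport,
        clock: Callable[[], float] = time.time,
    ) -> RegistryRecord:
        """Probe the endpoint; transport failure marks the record dead, never raises."""
        key = str(endpoint)
        record = self._records[key]
        try:
            fetched = fetch_description(endpoint, transport)
            alive, stale = True, fetched != record.description
        except Exception:
            alive, stale = False, record.stale
        updated = replace(record, alive=alive, stale=stale, last_checked=clock())
        self._store(updated)
        return updated

    # -- persistence -------------------------------------------------------

    def save(self, path: str):
        """Write a deterministic single-file JSON store."""
        payload = {
            key: {
                "description": _graph_to_sorted_nt(
                    emit_description(r.description)
                ),
                "ontology": _ontology_to_json(r.ontology),
                "alive": r.alive,
                "last_checked": r.last_checked,
                "stale": r.stale,
            }
            for key, r in sorted(self._records.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "Registry":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        reg = cls()
        for _, entry in sorted(payload.items()):
            g = Graph()
            g.parse(data=entry["description"], format="nt")
            desc = parse_description(g)
            ont = _ontology_from_json(entry["ontology"])
            input_def = ont.classes[desc.input_class]
            output_def = ont.classes[desc.output_class]
            reg._store(RegistryRecord(
                description=desc,
                input_def=input_def,
                output_def=output_def,
                ontology=ont,
                attached=frozenset(
                    attached_properties(input_def, output_def, ont)
                ),
                alive=entry["alive"],
                last_checked=entry["last_checked"],
                stale=entry["stale"],
            ))
        return reg


# -- JSON codecs for class definitions ------------------------------------


def _graph_to_sorted_nt(g: Graph) -> str:
    from rdflib.compare import to_canonical_graph  # content-derived bnode ids
    lines = to_canonical_graph(g).serialize(format="nt").strip().splitlines()
    return "\n".join(sorted(line for line in lines if line.strip()))


def _term_to_json(term):
    if term is None:
        return None
    if isinstance(term, Literal):
        return {
            "literal": str(term),
            "datatype": str(term.datatype) if term.datatype else None,
            "lang": term.language,
        }
    return {"iri": str(term)}


def _term_from_json(obj):
    if obj is None:
        return None
    if "iri" in obj:
        return URIRef(obj["iri"])
    return Literal(
        obj["literal"],
        datatype=URIRef(obj["datatype"]) if obj["datatype"] else None,
        lang=obj["lang"],
    )


def _ontology_to_json(ont: Ontology) -> dict:
    return {
        "classes": {
            str(iri): {
                "restrictions": [
                    {
                        "property": str(r.property),
                        "kind": r.kind.value,
                        "filler": _term_to_json(r.filler),
                        "min_count": r.min_count,
                    }
                    for r in cd.restrictions
                ],
                "superclasses": sorted(str(s) for s in cd.named_superclasses),
            }
            for iri, cd in sorted(ont.classes.items(), key=lambda kv: str(kv[0]))
        },
        "datatype_properties": sorted(str(p) for p in ont.datatype_properties),
    }


def _ontology_from_json(obj: dict) -> Ontology:
    ont = Ontology()
    for iri, entry in obj["classes"].items():
        restrictions = tuple(
            PropertyRestriction(
                URIRef(r["property"]),
                RestrictionKind(r["kind"]),
                _term_from_json(r["filler"]),
                r["min_count"],
            )
            for r in entry["restrictions"]
        )
        ont.classes[URIRef(iri)] = ClassDefinition(
            URIRef(iri), restrictions,
            frozenset(URIRef(s) for s in entry["superclasses"]),
        )
    ont.datatype_properties = {
        URIRef(p) for p in obj["datatype_properties"]
    }
    return ont
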