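"""Registry semantics: registration, discovery, menus, liveness, persistence."""

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from decorum.errors import RegistrationError
from decorum.fixtures.catalogue import build_decoys, build_hello_catalogue
from decorum.fixtures.hello import (HELLO, HELLO_ENDPOINT, HELLO_INPUT_ROOT,
                                    hello_invocation_graph)
from decorum.fixtures.synthetic import SyntheticSpec, build_random_catalogue
from decorum.fixtures.transport import (InMemoryTransport,
                                        catalogue_ontology_loader)
from decorum.host import HttpResponse
from decorum.registry import Registry


@pytest.fixture
def discovery_setup():
    """hello + 5 decoys, registered."""
    cat = build_hello_catalogue(include_async=False, include_param=False)
    cat = cat.merge(build_decoys(5))
    t = InMemoryTransport(cat)
    loader = catalogue_ontology_loader(cat)
    reg = Registry()
    for impl in cat.services.values():
        reg.register(impl.description.endpoint, t, loader)
    return reg, t, loader, cat


def _register_all(cat, clock=None):
    t = InMemoryTransport(cat)
    loader = catalogue_ontology_loader(cat)
    reg = Registry()
    for impl in cat.services.values():
        kwargs = {"clock": clock} if clock else {}
        reg.register(impl.description.endpoint, t, loader, **kwargs)
    return reg, t, loader


class TestRegister:
    def test_hello_record_attaches_exactly_the_greeting(self, discovery_setup):
        reg, *_ = discovery_setup
        record = next(r for r in reg.records
                      if r.description.endpoint == HELLO_ENDPOINT)
        assert record.attached == {HELLO.greeting}
        assert record.alive

    def test_non_rdf_endpoint_is_refused(self):
        class Junk:
            def get(self, iri):
                return HttpResponse(200, {"Content-Type": "text/html"},
                                    b"<html>hi</html>")
        with pytest.raises(RegistrationError):
            Registry().register(HELLO_ENDPOINT, Junk(), lambda c: None)

    def test_unresolvable_ontology_is_refused(self, transport):
        def broken_loader(cls):
            raise IOError("no ontology here")
        with pytest.raises(RegistrationError, match="unresolvable"):
            Registry().register(HELLO_ENDPOINT, transport, broken_loader)

    def test_reregistration_replaces_and_keeps_indexes_consistent(
            self, discovery_setup):
        reg, t, loader, _ = discovery_setup
        n_before = len(reg.records)
        reg.register(HELLO_ENDPOINT, t, loader)
        assert len(reg.records) == n_before
        hits = reg.find_by_property(HELLO.greeting)
        assert [str(r.description.endpoint) for r in hits] == [str(HELLO_ENDPOINT)]


class TestDiscovery:
    def test_named_node_matches_only_hello_among_decoys(self, discovery_setup):
        reg, *_ = discovery_setup
        g = hello_invocation_graph()
        hits = reg.find_by_input_instance(g, HELLO_INPUT_ROOT)
        assert [r.description.name for r in hits] == ["Hello"]
        # independent oracle: brute-force satisfies over every record
        from decorum.owl_model import satisfies
        expected = [r for r in reg.records
                    if satisfies(g, HELLO_INPUT_ROOT, r.input_def, r.ontology)[0]]
        assert hits == expected

    def test_restriction_free_input_class_matches_bare_nodes(self):
        cat = build_hello_catalogue(include_async=False, include_param=False)
        # a service that takes anything
        from rdflib.namespace import OWL
        from decorum.description import ServiceDescription
        from decorum.host import ServiceImplementation
        doc = Graph()
        doc.add((URIRef("http://x.org/any.owl#Anything"), RDF.type, OWL.Class))
        doc.add((URIRef("http://x.org/any.owl#Tagged"), RDF.type, OWL.Class))
        cat.ontologies["http://x.org/any.owl"] = doc
        desc = ServiceDescription(
            name="Omnivore", endpoint=URIRef("http://x.org/any"),
            input_class=URIRef("http://x.org/any.owl#Anything"),
            output_class=URIRef("http://x.org/any.owl#Tagged"))
        cat.add_service("omnivore",
                        ServiceImplementation(desc, lambda g, r, p: []))
        reg, *_ = _register_all(cat)
        bare = Graph()
        bare.add((HELLO_INPUT_ROOT, URIRef("http://x.org/p"), Literal("v")))
        hits = reg.find_by_input_instance(bare, HELLO_INPUT_ROOT)
        assert [r.description.name for r in hits] == ["Omnivore"]

    def test_by_type_fast_path_requires_explicit_typing(self, discovery_setup):
        reg, *_ = discovery_setup
        g = Graph()
        from rdflib.namespace import FOAF
        g.add((HELLO_INPUT_ROOT, FOAF.name, Literal("Foreign")))
        # structurally acceptable though untyped
        assert [r.description.name
                for r in reg.find_by_input_instance(g, HELLO_INPUT_ROOT)] == ["Hello"]
        assert reg.find_by_input_instance(g, HELLO_INPUT_ROOT,
                                          by_type_only=True) == []

    def test_find_by_property(self, discovery_setup):
        reg, *_ = discovery_setup
        assert [r.description.name
                for r in reg.find_by_property(HELLO.greeting)] == ["Hello"]
        assert reg.find_by_property(URIRef("http://x.org/nothing")) == []

    def test_menu_for_the_named_node(self, discovery_setup):
        reg, *_ = discovery_setup
        menu = reg.property_menu(hello_invocation_graph(), HELLO_INPUT_ROOT)
        assert {str(k): [r.description.name for r in v]
                for k, v in menu.items()} == {str(HELLO.greeting): ["Hello"]}

    def test_menu_of_unmatchable_node_is_empty(self, discovery_setup):
        reg, *_ = discovery_setup
        g = Graph()
        g.add((HELLO_INPUT_ROOT, URIRef("http://x.org/p"), Literal("v")))
        assert reg.property_menu(g, HELLO_INPUT_ROOT) == {}

    def test_menu_keys_equal_union_of_attached_over_matches(self, discovery_setup):
        reg, *_ = discovery_setup
        g = hello_invocation_graph()
        menu = reg.property_menu(g, HELLO_INPUT_ROOT)
        matches = reg.find_by_input_instance(g, HELLO_INPUT_ROOT)
        assert set(menu) == set().union(*(r.attached for r in matches))

    @pytest.mark.parametrize("seed", range(10))
    def test_index_consistency_on_random_catalogues(self, seed):
        cat = build_random_catalogue(SyntheticSpec(seed=seed))
        reg, *_ = _register_all(cat)
        all_props = {p for r in reg.records for p in r.attached}
        for record in reg.records:
            for p in all_props:
                hits = reg.find_by_property(p)
                assert (record in hits) == (p in record.attached)

    def test_registration_is_monotone_for_other_queries(self, discovery_setup):
        reg, t, loader, cat = discovery_setup
        before = reg.find_by_property(HELLO.greeting)
        extra = build_random_catalogue(SyntheticSpec(seed=99, n_services=2))
        t2 = InMemoryTransport(cat.merge(extra))
        loader2 = catalogue_ontology_loader(cat.merge(extra))
        for impl in extra.services.values():
            reg.register(impl.description.endpoint, t2, loader2)
        assert reg.find_by_property(HELLO.greeting) == before


class TestLiveness:
    def test_live_dead_and_stale(self, discovery_setup):
        reg, t, loader, cat = discovery_setup
        assert reg.check_alive(HELLO_ENDPOINT, t).alive

        class Dead:
            def get(self, iri):
                raise OSError("connection refused")
        updated = reg.check_alive(HELLO_ENDPOINT, Dead())
        assert not updated.alive
        # dead services are excluded from discovery by default
        assert reg.find_by_property(HELLO.greeting) == []
        assert [r.description.name for r in
                reg.find_by_property(HELLO.greeting, include_dead=True)
                ] == ["Hello"]

        class Changed:
            def get(self, iri):
                from decorum.description import emit_description
                from decorum.fixtures.hello import hello_description
                from decorum.rdf_core import serialize_graph
                from decorum.vocab import MEDIA_RDFXML
                d = hello_description()
                d = type(d)(**{**d.__dict__, "name": "Hello v2"})
                return HttpResponse(200, {"Content-Type": MEDIA_RDFXML},
                                    serialize_graph(emit_description(d),
                                                    MEDIA_RDFXML))
        updated = reg.check_alive(HELLO_ENDPOINT, Changed())
        assert updated.alive and updated.stale


class TestPersistence:
    def test_save_load_round_trip_preserves_discovery(self, discovery_setup,
                                                      tmp_path):
        reg, *_ = discovery_setup
        path = tmp_path / "registry.json"
        reg.save(str(path))
        loaded = Registry.load(str(path))
        assert [str(r.description.endpoint) for r in loaded.records] == \
               [str(r.description.endpoint) for r in reg.records]
        menu = loaded.property_menu(hello_invocation_graph(), HELLO_INPUT_ROOT)
        assert set(menu) == {HELLO.greeting}

    def test_serialization_is_deterministic(self, discovery_setup, tmp_path):
        reg, *_ = discovery_setup
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        reg.save(str(a))
        Registry.load(str(a)).save(str(b))
        assert a.read_bytes() == b.read_bytes()
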