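"""Service kernel: GET/POST protocol, multiplexing, async polling, parameters."""

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import FOAF, RDF, RDFS

from decorum.description import parse_description
from decorum.errors import AmbiguousParameterError
from decorum.fixtures.hello import (HELLO, HELLO_INPUT_ROOT, build_hello,
                                    build_parameterized_hello,
                                    hello_invocation_graph,
                                    hello_invocation_message)
from decorum.host import ServiceHost, ServiceImplementation, extract_parameters
from decorum.rdf_core import (MEDIA_N3, MEDIA_RDFXML, graph_union,
                              graphs_isomorphic, parse_graph, serialize_graph)
from decorum.vocab import SERVICE_ERROR


@pytest.fixture
def host():
    return ServiceHost(build_hello("sync"))


@pytest.fixture
def async_host():
    return ServiceHost(build_hello("async"), pending_polls=1)


def _post(host, names=("Guy Incognito",), media=MEDIA_RDFXML):
    return host.handle_post(
        serialize_graph(hello_invocation_graph(names), media), media)


class TestGet:
    def test_returns_parseable_description(self, host):
        resp = host.handle_get()
        assert resp.status == 200 and resp.media_type == MEDIA_RDFXML
        d = parse_description(parse_graph(resp.body, MEDIA_RDFXML))
        assert d == host.impl.description

    def test_get_is_stateless_and_byte_identical(self, host):
        assert host.handle_get().body == host.handle_get().body


class TestPostSync:
    def test_decorates_and_preserves_the_root_iri(self, host):
        resp = _post(host)
        assert resp.status == 200
        out = parse_graph(resp.body, resp.media_type)
        assert (HELLO_INPUT_ROOT, HELLO.greeting,
                Literal("Hello, Guy Incognito!")) in out
        assert (HELLO_INPUT_ROOT, RDF.type, HELLO.GreetedIndividual) in out
        roots = {s for s in out.subjects()}
        assert roots == {HELLO_INPUT_ROOT}

    def test_same_body_twice_is_isomorphic(self, host):
        a = parse_graph(_post(host).body, MEDIA_RDFXML)
        b = parse_graph(_post(host).body, MEDIA_RDFXML)
        assert graphs_isomorphic(a, b)

    def test_accept_header_selects_n3(self, host):
        resp = host.handle_post(hello_invocation_message(), MEDIA_RDFXML,
                                accept=MEDIA_N3)
        assert resp.media_type == MEDIA_N3
        assert (HELLO_INPUT_ROOT, HELLO.greeting,
                Literal("Hello, Guy Incognito!")) in parse_graph(
                    resp.body, MEDIA_N3)

    def test_multiplexed_response_is_union_of_single_root_responses(self, host):
        names = ("Ada", "Grace", "Barbara")
        multi = parse_graph(_post(host, names).body, MEDIA_RDFXML)
        # each single-root invocation uses its own root IRI
        g = hello_invocation_graph(names)
        single_graphs = []
        for root in sorted(g.subjects(RDF.type, HELLO.NamedIndividual)):
            body = serialize_graph(
                hello_invocation_graph(
                    tuple(str(n) for n in g.objects(root, FOAF.name)),
                    roots=(root,)),
                MEDIA_RDFXML)
            single_graphs.append(parse_graph(
                host.handle_post(body, MEDIA_RDFXML).body, MEDIA_RDFXML))
        assert graphs_isomorphic(multi, graph_union(*single_graphs))

    def test_wrong_class_is_a_client_fault_naming_the_expected_class(self, host):
        g = Graph()
        g.add((HELLO_INPUT_ROOT, RDF.type, HELLO.GreetedIndividual))
        resp = host.handle_post(serialize_graph(g, MEDIA_RDFXML), MEDIA_RDFXML)
        assert resp.status == 400
        assert str(HELLO.NamedIndividual) in resp.body.decode()

    def test_malformed_body_and_unknown_media_are_client_faults(self, host):
        assert host.handle_post(b"<broken", MEDIA_RDFXML).status == 400
        assert host.handle_post(b"x=1", "application/x-www-form-urlencoded"
                                ).status == 400

    def test_provider_fault_on_single_root_is_a_server_error(self):
        def explode(g, root, params):
            raise RuntimeError("backend down")
        impl = ServiceImplementation(build_hello("sync").description, explode)
        resp = ServiceHost(impl).handle_post(
            hello_invocation_message(), MEDIA_RDFXML)
        assert resp.status == 500
        out = parse_graph(resp.body, resp.media_type)
        assert next(out.objects(HELLO_INPUT_ROOT, SERVICE_ERROR), None) is not None

    def test_partial_failure_leaves_other_roots_unaffected(self):
        def moody(g, root, params):
            name = next(g.objects(root, FOAF.name))
            if str(name) == "FAIL":
                raise RuntimeError("no greeting for you")
            return [(root, HELLO.greeting, Literal(f"Hello, {name}!"))]
        impl = ServiceImplementation(build_hello("sync").description, moody)
        resp = ServiceHost(impl).handle_post(
            serialize_graph(hello_invocation_graph(("Ada", "FAIL")),
                            MEDIA_RDFXML), MEDIA_RDFXML)
        assert resp.status == 200
        out = parse_graph(resp.body, resp.media_type)
        ok_roots = [s for s in out.subjects(HELLO.greeting, None)]
        bad_roots = [s for s in out.subjects(SERVICE_ERROR, None)]
        assert len(ok_roots) == 1 and len(bad_roots) == 1
        assert ok_roots[0] != bad_roots[0]


class TestPostAsync:
    def test_immediate_202_with_poll_reference_per_root(self, async_host):
        resp = _post(async_host)
        assert resp.status == 202
        assert resp.header("Retry-After") == "5"
        stub = parse_graph(resp.body, resp.media_type)
        poll = stub.value(HELLO_INPUT_ROOT, RDFS.isDefinedBy)
        assert poll is not None
        assert str(poll).startswith(str(async_host.impl.description.endpoint))
        assert (HELLO_INPUT_ROOT, RDF.type, HELLO.GreetedIndividual) in stub

    def test_multiplexed_roots_get_distinct_poll_iris(self, async_host):
        stub = parse_graph(_post(async_host, ("A", "B", "C")).body, MEDIA_RDFXML)
        polls = list(stub.objects(None, RDFS.isDefinedBy))
        assert len(polls) == 3 and len(set(polls)) == 3

    def test_malformed_body_registers_no_tasks(self, async_host):
        assert async_host.handle_post(b"<broken", MEDIA_RDFXML).status == 400
        assert async_host.tasks == {}

    def test_poll_302_while_pending_then_200_with_sync_equivalent_graph(
            self, async_host, host):
        stub = parse_graph(_post(async_host).body, MEDIA_RDFXML)
        poll_iri = str(stub.value(HELLO_INPUT_ROOT, RDFS.isDefinedBy))
        task_id = poll_iri.rsplit("/", 1)[1]
        pending = async_host.handle_poll(task_id)
        assert pending.status == 302
        assert pending.header("Location") == poll_iri
        assert pending.header("Retry-After") == "5"
        done = async_host.handle_poll(task_id)
        assert done.status == 200
        sync_out = parse_graph(_post(host).body, MEDIA_RDFXML)
        assert graphs_isomorphic(parse_graph(done.body, done.media_type),
                                 sync_out)

    def test_unknown_task_is_404(self, async_host):
        assert async_host.handle_poll("task-999").status == 404

    def test_completed_results_expire(self):
        now = [0.0]
        h = ServiceHost(build_hello("async"), clock=lambda: now[0],
                        task_retention_s=3600)
        stub = parse_graph(_post(h).body, MEDIA_RDFXML)
        task_id = str(stub.value(HELLO_INPUT_ROOT, RDFS.isDefinedBy)
                      ).rsplit("/", 1)[1]
        assert h.handle_poll(task_id).status == 200
        now[0] = 3599.0
        assert h.handle_poll(task_id).status == 200
        now[0] = 3601.0
        assert h.handle_poll(task_id).status == 404
        assert h.handle_poll(task_id).status == 404  # gone for good


class TestParameters:
    def _message(self, punct=None, extra_node=False):
        g = hello_invocation_graph()
        if punct is not None:
            node = URIRef("http://example.org/params#1")
            g.add((node, RDF.type, HELLO.GreetingParameters))
            g.add((node, HELLO.punctuation, Literal(punct)))
        if extra_node:
            node2 = URIRef("http://example.org/params#2")
            g.add((node2, RDF.type, HELLO.GreetingParameters))
        return g

    def test_parameter_node_is_extracted_with_its_values(self):
        params = extract_parameters(self._message("?!"),
                                    HELLO.GreetingParameters)
        assert params.first(HELLO.punctuation) == Literal("?!")

    def test_absent_parameters_mean_service_defaults(self):
        assert extract_parameters(self._message(),
                                  HELLO.GreetingParameters) is None
        h = ServiceHost(build_parameterized_hello("sync"))
        out = parse_graph(h.handle_post(
            serialize_graph(self._message(), MEDIA_RDFXML),
            MEDIA_RDFXML).body, MEDIA_RDFXML)
        assert (HELLO_INPUT_ROOT, HELLO.greeting,
                Literal("Hello, Guy Incognito!")) in out

    def test_parameters_alter_the_decoration(self):
        h = ServiceHost(build_parameterized_hello("sync"))
        out = parse_graph(h.handle_post(
            serialize_graph(self._message("?"), MEDIA_RDFXML),
            MEDIA_RDFXML).body, MEDIA_RDFXML)
        assert (HELLO_INPUT_ROOT, HELLO.greeting,
                Literal("Hello, Guy Incognito?")) in out

    def test_two_parameter_nodes_are_ambiguous(self):
        with pytest.raises(AmbiguousParameterError):
            extract_parameters(self._message("!", extra_node=True),
                               HELLO.GreetingParameters)
        h = ServiceHost(build_parameterized_hello("sync"))
        resp = h.handle_post(
            serialize_graph(self._message("!", extra_node=True), MEDIA_RDFXML),
            MEDIA_RDFXML)
        assert resp.status == 400
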