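"""Service-side kernel.

Wraps a provider-supplied annotation function in the full messaging
protocol:

* ``GET`` on the endpoint returns the interface document;
* ``POST`` of an RDF graph invokes the service on every URI-named root
  typed with the input class (multiplexing), returning the concatenation of
  the per-root outputs with the *same root IRIs*, each re-typed with the
  output class;
* in asynchronous mode the POST answers ``202`` immediately, each root
  decorated with an ``rdfs:isDefinedBy`` polling URL that yields ``302``
  while pending and ``200`` with the root's output graph when complete;
* control parameters travel as an independently-typed node inside the same
  invocation graph — the POST body is the whole message, no FORM encoding
  is ever read.

Statuses: the protocol itself needs only 200/202/302; client faults map to
400, unknown or expired polling URLs to 404, provider faults to 500 —
standard HTTP semantics throughout.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from .description import ServiceDescription
from .errors import (AmbiguousParameterError, GraphParseError,
                     UnsupportedMediaTypeError)
from .rdf_core import extract_typed_roots, parse_graph, serialize_graph
from .vocab import MEDIA_N3, MEDIA_RDFXML, SERVICE_ERROR

log = logging.getLogger(__name__)

DEFAULT_RETRY_AFTER_S = 5
DEFAULT_TASK_RETENTION_S = 3600.0


@dataclass
class HttpResponse:
    status: int
    headers: dict[str, str] = field(default_factory=dict)
    body: bytes = b""

    def header(self, name: str, default: str = "") -> str:
        for key, value in self.headers.items():
            if key.lower() == name.lower():
                return value
        return default

    @property
    def media_type(self) -> str:
        return self.header("Content-Type").split(";")[0].strip()


@dataclass(frozen=True)
class ParameterInstance:
    """The control-parameter node of an invocation graph."""

    node: URIRef
    values: dict[URIRef, tuple]

    def first(self, prop: URIRef, default=None):
        vals = self.values.get(prop)
        return vals[0] if vals else default


#: Provider business logic: given the invocation graph, one root, and the
#: optional parameter instance, return the triples to attach.  Must be pure
#: per root so multiplexed roots can run in any order.
AnnotateFn = Callable[[Graph, URIRef, Optional[ParameterInstance]], Iterable[tuple]]


@dataclass
class ServiceImplementation:
    description: ServiceDescription
    annotate: AnnotateFn
    mode: str = "sync"  # "sync" | "async"

    def __post_init__(self):
        if self.mode not in ("sync", "async"):
            raise ValueError(f"mode must be 'sync' or 'async', got {self.mode!r}")


@dataclass
class AsyncTask:
    task_id: str
    poll_iri: URIRef
    root: URIRef
    compute: Callable[[], Graph]
    pending_polls: int
    retry_after_s: int
    result: Optional[Graph] = None
    completed_at: Optional[float] = None

    @property
    def status(self) -> str:
        return "complete" if self.result is not None else "pending"


def extract_parameters(
    g: Graph, parameter_class: URIRef
) -> Optional[ParameterInstance]:
    """Find the unique control-parameter node typed with ``parameter_class``.

    Absent → ``None`` (service defaults apply); more than one node is an
    ambiguous configuration and an error.
    """
    nodes = sorted(
        (n for n in g.subjects(RDF.type, parameter_class) if isinstance(n, URIRef)),
        key=str,
    )
    if not nodes:
        return None
    if len(nodes) > 1:
        raise AmbiguousParameterError(
            f"{len(nodes)} nodes typed {parameter_class}; expected at most one"
        )
    node = nodes[0]
    values: dict[URIRef, tuple] = {}
    for p, o in sorted(g.predicate_objects(node), key=lambda po: (str(po[0]), str(po[1]))):
        if p == RDF.type:
            continue
        values.setdefault(p, ())
        values[p] = values[p] + (o,)
    return ParameterInstance(node, values)


class ServiceHost:
    """Protocol engine for one service implementation."""

    def __init__(
        self,
        impl: ServiceImplementation,
        retry_after_s: int = DEFAULT_RETRY_AFTER_S,
        pending_polls: int = 0,
        task_retention_s: float = DEFAULT_TASK_RETENTION_S,
        clock: Callable[[], float] = time.time,
    ):
        self.impl = impl
        self.retry_after_s = retry_after_s
        #: number of polls a task answers 302 before computing (test knob)
        self.pending_polls = pending_polls
        self.task_retention_s = task_retention_s
        self.clock = clock
        self.tasks: dict[str, AsyncTask] = {}
        self._task_ids = itertools.count(1)
        self._get_body: Optional[bytes] = None

    # -- GET ---------------------------------------------------------------

    def handle_get(self) -> HttpResponse:
        if self._get_body is None:
            from .description import emit_description
            self._get_body = serialize_graph(
                emit_description(self.impl.description), MEDIA_RDFXML
            )
        return HttpResponse(200, {"Content-Type": MEDIA_RDFXML}, self._get_body)

    # -- POST --------------------------------------------------------------

    def handle_post(
        self, body: bytes, media_type: str, accept: Optional[str] = None
    ) -> HttpResponse:
        if self.impl.mode == "async":
            return self.handle_post_async(body, media_type, accept)
        return self.handle_post_sync(body, media_type, accept)

    def _response_media(self, accept: Optional[str]) -> str:
        if accept and "n3" in accept:
            return MEDIA_N3
        return MEDIA_RDFXML

    def _prepare(self, body: bytes, media_type: str):
        """Parse the invocation message; returns (graph, roots, params) or an error response."""
        try:
            g = parse_graph(body, media_type)
        except (UnsupportedMediaTypeError, GraphParseError) as exc:
            return None, HttpResponse(
                400, {"Content-Type": "text/plain"}, str(exc).encode()
            )
        desc = self.impl.description
        roots = extract_typed_roots(g, desc.input_class)
        if not roots:
            msg = (
                f"invocation graph contains no URI-named individual typed "
                f"{desc.input_class}"
            )
            return None, HttpResponse(400, {"Content-Type": "text/plain"}, msg.encode())
        try:
            params = (
                extract_parameters(g, desc.parameter_class)
                if desc.parameter_class is not None
                else None
            )
        except AmbiguousParameterError as exc:
            return None, HttpResponse(
                400, {"Content-Type": "text/plain"}, str(exc).encode()
            )
        return (g, roots, params), None

    def _run_root(self, g: Graph, root: URIRef, params) -> Graph:
        out = Graph()
        out.add((root, RDF.type, self.impl.description.output_class))
        for t in self.impl.annotate(g, root, params):
            out.add(t)
        return out

    def handle_post_sync(
        self, body: bytes, media_type: str, accept: Optional[str] = None
    ) -> HttpResponse:
        prepared, err = self._prepare(body, media_type)
        if err is not None:
            return err
        g, roots, params = prepared
        out = Graph()
        failures = 0
        for root in roots:  # independent runs; output is their concatenation
            try:
                for t in self._run_root(g, root, params):
                    out.add(t)
            except Exception as exc:
                log.exception("annotate failed for root %s", root)
                failures += 1
                out.add((root, SERVICE_ERROR, Literal(str(exc))))
        status = 500 if failures == len(roots) else 200
        media = self._response_media(accept)
        return HttpResponse(status, {"Content-Type": media},
                            serialize_graph(out, media))

    def handle_post_async(
        self, body: bytes, media_type: str, accept: Optional[str] = None
    ) -> HttpResponse:
        prepared, err = self._prepare(body, media_type)
        if err is not None:
            return err
        g, roots, params = prepared
        stub = Graph()
        endpoint = str(self.impl.description.endpoint)
        for root in roots:
            task_id = f"task-{next(self._task_ids)}"
            poll_iri = URIRef(f"{endpoint}/task/{task_id}")
            self.tasks[task_id] = AsyncTask(
                task_id=task_id,
                poll_iri=poll_iri,
                root=root,
                compute=lambda g=g, root=root, params=params: self._run_root(
                    g, root, params
                ),
                pending_polls=self.pending_polls,
                retry_after_s=self.retry_after_s,
            )
            stub.add((root, RDFS.isDefinedBy, poll_iri))
            stub.add((root, RDF.type, self.impl.description.output_class))
        media = self._response_media(accept)
        return HttpResponse(
            202,
            {"Content-Type": media, "Retry-After": str(self.retry_after_s)},
            serialize_graph(stub, media),
        )

    # -- polling -----------------------------------------------------------

    def handle_poll(self, task_id: str, accept: Optional[str] = None) -> HttpResponse:
        task = self.tasks.get(task_id)
        if task is None:
            return HttpResponse(
                404, {"Content-Type": "text/plain"},
                f"unknown or expired task {task_id!r}".encode(),
            )
        if task.pending_polls > 0:
            task.pending_polls -= 1
            return HttpResponse(
                302,
                {"Location": str(task.poll_iri),
                 "Retry-After": str(task.retry_after_s)},
            )
        if task.result is None:
            try:
                task.result = task.compute()
            except Exception as exc:
                log.exception("async annotate failed for root %s", task.root)
                err = Graph()
                err.add((task.root, SERVICE_ERROR, Literal(str(exc))))
                task.result = err
            task.completed_at = self.clock()
        elif (
            task.completed_at is not None
            and self.clock() - task.completed_at > self.task_retention_s
        ):
            del self.tasks[task_id]
            return HttpResponse(
                404, {"Content-Type": "text/plain"},
                f"task {task_id!r} has expired".encode(),
            )
        media = self._response_media(accept)
        return HttpResponse(
            200, {"Content-Type": media}, serialize_graph(task.result, media)
        )
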