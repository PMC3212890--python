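"""Socket transport: a WSGI front for service hosts and a raw HTTP client.

The client transport is built on :mod:`http.client` rather than a
higher-level library because polling requires seeing ``302`` responses
rather than having them auto-followed.

The WSGI app serves each host under its endpoint's path, so a host whose
description endpoint is ``http://127.0.0.1:PORT/hello`` answers
``GET /hello``, ``POST /hello`` and ``GET /hello/task/<id>``.
"""

from __future__ import annotations

import http.client
import threading
from typing import Optional
from urllib.parse import urlsplit
from wsgiref.simple_server import WSGIRequestHandler, make_server

from .errors import TransportError
from .host import HttpResponse, ServiceHost

_REASON = {200: "OK", 202: "Accepted", 302: "Found", 400: "Bad Request",
           404: "Not Found", 405: "Method Not Allowed",
           500: "Internal Server Error"}


def make_wsgi_app(hosts: dict[str, ServiceHost]):
    """WSGI application routing request paths to hosts.

    ``hosts`` maps a URL path (e.g. ``"/hello"``) to its host.
    """

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "/")
        method = environ.get("REQUEST_METHOD", "GET")
        resp = _dispatch(hosts, method, path, environ)
        status_line = f"{resp.status} {_REASON.get(resp.status, 'Unknown')}"
        headers = list(resp.headers.items())
        if resp.body:
            headers.append(("Content-Length", str(len(resp.body))))
        start_response(status_line, headers)
        return [resp.body]

    return app


def _dispatch(hosts, method, path, environ) -> HttpResponse:
    for mount, host in hosts.items():
        if path == mount:
            if method == "GET":
                return host.handle_get()
            if method == "POST":
                length = int(environ.get("CONTENT_LENGTH") or 0)
                body = environ["wsgi.input"].read(length)
                return host.handle_post(
                    body,
                    environ.get("CONTENT_TYPE", ""),
                    environ.get("HTTP_ACCEPT"),
                )
            return HttpResponse(405, {"Allow": "GET, POST"})
        prefix = mount + "/task/"
        if path.startswith(prefix) and method == "GET":
            return host.handle_poll(path[len(prefix):],
                                    environ.get("HTTP_ACCEPT"))
    return HttpResponse(404, {"Content-Type": "text/plain"},
                        f"no service mounted at {path}".encode())


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args):  # tests should not spam stderr
        pass


class LocalServer:
    """A wsgiref server on an ephemeral port, run in a daemon thread."""

    def __init__(self, hosts: dict[str, ServiceHost], port: int = 0):
        self._server = make_server(
            "127.0.0.1", port, make_wsgi_app(hosts), handler_class=_QuietHandler
        )
        self.port = self._server.server_port
        self.base_url = f"http://127.0.0.1:{self.port}"
        self._thread: Optional[threading.Thread] = None

    def __enter__(self):
        self._thread = threading.Thread(
            target=self._server.serve_forever, daemon=True
        )
        self._thread.start()
        return self

    def __exit__(self, *exc):
        self._server.shutdown()
        self._server.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def serve_forever(self):
        self._server.serve_forever()


class HttpClientTransport:
    """Minimal HTTP transport; never follows redirects."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def _request(self, method, iri, body=None, headers=None) -> HttpResponse:
        parts = urlsplit(iri)
        if parts.scheme != "http":
            raise TransportError(f"only http:// IRIs are dereferenceable: {iri}")
        conn = http.client.HTTPConnection(
            parts.hostname, parts.port or 80, timeout=self.timeout
        )
        path = parts.path or "/"
        if parts.query:
            path += "?" + parts.query
        try:
            conn.request(method, path, body=body, headers=headers or {})
            raw = conn.getresponse()
            resp = HttpResponse(raw.status, dict(raw.getheaders()), raw.read())
        except OSError as exc:
            raise TransportError(f"{method} {iri} failed: {exc}") from exc
        finally:
            conn.close()
        return resp

    def get(self, iri: str) -> HttpResponse:
        return self._request("GET", iri)

    def post(self, iri: str, body: bytes, content_type: str,
             accept: Optional[str] = None) -> HttpResponse:
        headers = {"Content-Type": content_type}
        if accept:
            headers["Accept"] = accept
        return self._request("POST", iri, body=body, headers=headers)
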