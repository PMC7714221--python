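"""Read-only HTTP access: native REST (/v1/...) and refget endpoints.

Both surfaces are served by a single WSGI application backed by one
:class:`~seqvault.repo.SeqVault` instance, so their responses are
byte-identical for the same slice.

Native surface
    ``GET /v1/ping``                      service info (JSON)
    ``GET /v1/sequence/{ir}?start&end``   plain-text subsequence
    ``GET /v1/metadata/{ir}``             length/alphabet/aliases (JSON)
    ``{ir}`` is a CURIE (``refseq:NM_...``) or a globally unique bare
    alias. Errors: 400 malformed parameters, 404 unknown, 422 bad range
    or ambiguous alias (candidates listed in the body).

refget surface (digest queries only — namespaced identifiers are 404)
    ``GET /sequence/service-info``
    ``GET /sequence/{digest}?start&end``  (md5 hex, sha512t24u,
    ``SQ.<sha512t24u>`` or 48-hex trunc512 all accepted)
    ``GET /sequence/{digest}/metadata``
    Errors follow refget conventions: 416 out-of-bounds range, 501 for
    start > end (circular semantics, unsupported), 400 malformed.
    Range headers are not supported; start/end query parameters only.

Only GET is accepted (anything else is 405): the HTTP surfaces are
strictly read-only. Sequence bodies are streamed in fixed-size chunks so
peak memory does not grow with slice length.
"""

from __future__ import annotations

import base64
import binascii
import json
import re
import threading
from typing import Callable, Iterable
from urllib.parse import parse_qs, unquote
from wsgiref.simple_server import WSGIRequestHandler, WSGIServer, make_server

from . import __version__
from .exceptions import AmbiguousIdentifierError, NotFoundError, RangeError
from .repo import SeqVault

__all__ = ["create_app", "serve", "BackgroundServer", "CHUNK_SIZE"]

CHUNK_SIZE = 64 * 1024

REFGET_MEDIA_TYPE = "text/vnd.ga4gh.refget.v1.0.1+plain"
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")
_TRUNC512_RE = re.compile(r"^[0-9a-f]{48}$")
_B64URL32_RE = re.compile(r"^[A-Za-z0-9_-]{32}$")

_STATUS = {
    200: "200 OK",
    400: "400 Bad Request",
    404: "404 Not Found",
    405: "405 Method Not Allowed",
    416: "416 Range Not Satisfiable",
    422: "422 Unprocessable Entity",
    501: "501 Not Implemented",
}


class _HttpError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


def _parse_coord(qs: dict, name: str) -> int | None:
    vals = qs.get(name)
    if not vals:
        return None
    try:
        value = int(vals[0])
    except ValueError:
        raise _HttpError(400, f"query parameter {name!r} must be an integer")
    if value < 0:
        raise _HttpError(400, f"query parameter {name!r} must be non-negative")
    return value


def _trunc512_to_sha512t24u(hex_digest: str) -> str:
    raw = binascii.unhexlify(hex_digest)
    return base64.urlsafe_b64encode(raw).decode("ascii")


def _sha512t24u_to_trunc512(digest: str) -> str:
    return binascii.hexlify(base64.urlsafe_b64decode(digest)).decode("ascii")


def create_app(repo: SeqVault, service_name: str = "seqvault") -> Callable:
    """Build the WSGI application serving both HTTP surfaces of ``repo``."""

    def resolve_native(ir: str) -> str:
        try:
            return repo._resolve(ir)
        except AmbiguousIdentifierError as exc:
            raise _HttpError(
                422,
                f"ambiguous alias {exc.alias!r}; candidate namespaces: "
                + ", ".join(exc.namespaces),
            )
        except NotFoundError:
            raise _HttpError(404, f"unknown identifier: {ir}")

    def resolve_refget(digest: str) -> str:
        """Map a bare refget digest (any accepted spelling) to a seq_id."""
        if ":" in digest:
            # refget queries use digests, never namespaced identifiers
            raise _HttpError(404, f"not a digest: {digest}")
        candidates = []
        if _MD5_RE.match(digest):
            candidates.append(("MD5", digest))
        if _B64URL32_RE.match(digest):
            candidates.append(("sha512t24u", digest))
        if digest.startswith("SQ.") and _B64URL32_RE.match(digest[3:]):
            candidates.append(("sha512t24u", digest[3:]))
        if _TRUNC512_RE.match(digest):
            candidates.append(("sha512t24u", _trunc512_to_sha512t24u(digest)))
        for namespace, alias in candidates:
            seq_ids = repo._aliases.translate(alias, namespace=namespace)
            if seq_ids:
                return seq_ids[0]
        raise _HttpError(404, f"unknown digest: {digest}")

    def check_range(length: int, start: int | None, end: int | None, refget: bool):
        s = 0 if start is None else start
        e = length if end is None else end
        if s > e:
            if refget:
                # start > end implies circular coordinates, which are
                # not supported on linear sequences
                raise _HttpError(501, "start > end: circular sequences are not supported")
            raise _HttpError(422, f"start ({s}) > end ({e})")
        if e > length or s > length:
            raise _HttpError(416 if refget else 422,
                             f"range [{s}, {e}) exceeds sequence length {length}")
        return s, e

    def stream_sequence(seq_id: str, start: int, end: int) -> Iterable[bytes]:
        pos = start
        while pos < end:
            stop = min(pos + CHUNK_SIZE, end)
            yield repo._fastadir.fetch(seq_id, pos, stop).encode("ascii")
            pos = stop
        if start == end:
            yield b""

    def native_metadata(seq_id: str) -> dict:
        rec = repo._fastadir.info(seq_id)
        aliases = [str(c) for c in repo.translate_identifier(f"sha512t24u:{seq_id}")]
        return {
            "added": rec.added,
            "length": rec.len,
            "alphabet": rec.alpha,
            "aliases": aliases,
        }

    def refget_metadata(seq_id: str) -> dict:
        rec = repo._fastadir.info(seq_id)
        current = repo._aliases.find_aliases(seq_id=seq_id, current_only=True)
        md5 = next((r.alias for r in current if r.namespace == "MD5"), None)
        return {
            "metadata": {
                "id": seq_id,
                "md5": md5,
                "trunc512": _sha512t24u_to_trunc512(seq_id),
                "ga4gh": f"SQ.{seq_id}",
                "length": rec.len,
                "aliases": [
                    {"naming_authority": r.namespace, "alias": r.alias} for r in current
                ],
            }
        }

    def service_info_native() -> dict:
        st = repo.stats()
        return {
            "service_name": service_name,
            "version": __version__,
            "repository_root": str(repo.root),
            "n_sequences": st.n_sequences,
        }

    def service_info_refget() -> dict:
        return {
            "service": {
                "circular_supported": False,
                "algorithms": ["md5", "trunc512", "ga4gh"],
                "subsequence_limit": None,
                "supported_api_versions": ["1.0"],
            }
        }

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = unquote(environ.get("PATH_INFO", "") or "/")
        qs = parse_qs(environ.get("QUERY_STRING", ""))

        def respond(status: int, body: bytes | Iterable[bytes], ctype: str):
            headers = [("Content-Type", ctype)]
            if isinstance(body, bytes):
                headers.append(("Content-Length", str(len(body))))
                body = [body]
            start_response(_STATUS[status], headers)
            return body

        def respond_json(payload: dict, status: int = 200):
            return respond(status, json.dumps(payload, indent=2).encode(), "application/json")

        try:
            if method != "GET":
                raise _HttpError(405, "read-only interface: only GET is supported")

            if path == "/v1/ping":
                return respond_json(service_info_native())

            if path.startswith("/v1/sequence/"):
                ir = path[len("/v1/sequence/"):]
                seq_id = resolve_native(ir)
                length = repo._fastadir.info(seq_id).len
                start, end = check_range(
                    length, _parse_coord(qs, "start"), _parse_coord(qs, "end"), refget=False
                )
                return respond(200, stream_sequence(seq_id, start, end), "text/plain")

            if path.startswith("/v1/metadata/"):
                ir = path[len("/v1/metadata/"):]
                return respond_json(native_metadata(resolve_native(ir)))

            if path == "/sequence/service-info":
                return respond_json(service_info_refget())

            if path.startswith("/sequence/") and path.endswith("/metadata"):
                digest = path[len("/sequence/"):-len("/metadata")]
                return respond_json(refget_metadata(resolve_refget(digest)))

            if path.startswith("/sequence/"):
                digest = path[len("/sequence/"):]
                seq_id = resolve_refget(digest)
                length = repo._fastadir.info(seq_id).len
                start, end = check_range(
                    length, _parse_coord(qs, "start"), _parse_coord(qs, "end"), refget=True
                )
                return respond(200, stream_sequence(seq_id, start, end), REFGET_MEDIA_TYPE)

            raise _HttpError(404, f"no such route: {path}")
        except _HttpError as exc:
            return respond_json({"error": exc.message}, status=exc.status)
        except RangeError as exc:  # defensive: repo-level range failures
            return respond_json({"error": str(exc)}, status=422)

    return app


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format, *args):  # per-request access log is noise here
        pass


class BackgroundServer:
    """A wsgiref server on a daemon thread, for tests and local use."""

    def __init__(self, repo: SeqVault, host: str = "127.0.0.1", port: int = 0):
        self._httpd: WSGIServer = make_server(
            host, port, create_app(repo), handler_class=_QuietHandler
        )
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def __enter__(self) -> "BackgroundServer":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        self._thread.join(timeout=5)


def serve(repo: SeqVault, host: str = "127.0.0.1", port: int = 5000) -> None:
    """Serve both HTTP surfaces until interrupted."""
    with make_server(host, port, create_app(repo)) as httpd:
        httpd.serve_forever()
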