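"""Read-only web resources over a Dataset: HTML, XML, FASTA (and JSON).

Every entity kind has a collection URL (``/precursors``) and a member URL
(``/precursors/hsa-mir-21``); every declared association becomes a nested
URL on its owner (``/matures/hsa-miR-21/papers``,
``/precursors/hsa-mir-21/species``).  Representations are negotiated by
path suffix first (``.xml``/``.fasta``/``.html``/``.json``), then by the
Accept header, defaulting to HTML.  FASTA is only offered where the
resource carries sequences.  The full route table is self-describing via
``/described_routes.txt`` and ``/described_routes.xml``.

The service is strictly read-only: only GET is accepted and no request
mutates the dataset (provable via :meth:`mirhub.model.Dataset.fingerprint`).
"""

from __future__ import annotations

import html as _html
import json
import re
from dataclasses import dataclass, field
from typing import Optional
from urllib.parse import parse_qs, quote, unquote
from xml.etree import ElementTree as ET

from .model import Dataset, Registry

MEDIA_TYPES = {
    "html": "text/html; charset=utf-8",
    "xml": "application/xml; charset=utf-8",
    "fasta": "text/plain; charset=utf-8",
    "json": "application/json; charset=utf-8",
    "txt": "text/plain; charset=utf-8",
}

_ACCEPT_TO_FORMAT = (
    ("application/xml", "xml"),
    ("text/xml", "xml"),
    ("application/json", "json"),
    ("text/plain", "fasta"),
    ("text/html", "html"),
)

DEFAULT_PER_PAGE = 100


@dataclass(frozen=True)
class ResourceRoute:
    """One canonical URL template with its renderable representations."""

    path_template: str
    kind: str
    association: Optional[str] = None
    cardinality: str = "many"
    representations: tuple = ("html", "xml")


@dataclass
class ResourceResponse:
    status: int
    media_type: str
    body: bytes


def encode_identifier(identifier: str) -> str:
    """Percent-encode an identifier for a path segment; '*' stays literal."""
    return quote(str(identifier), safe="*")


class Service:
    """Binds a Dataset to the uniform resource surface."""

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self.registry: Registry = dataset.registry

    # -- route table -------------------------------------------------------

    def routes(self) -> list:
        reg = self.registry
        out = []
        out.append(ResourceRoute("/described_routes.txt", "_meta",
                                 representations=("txt",)))
        out.append(ResourceRoute("/described_routes.xml", "_meta",
                                 representations=("xml",)))
        for kind, info in reg.kinds.items():
            reps = ["html", "xml", "json"]
            if info.sequence_bearing:
                reps.append("fasta")
            out.append(ResourceRoute(f"/{info.plural}", kind,
                                     cardinality="many",
                                     representations=tuple(reps)))
            out.append(ResourceRoute(f"/{info.plural}/{{id}}", kind,
                                     cardinality="one",
                                     representations=tuple(reps)))
            for name, assoc in sorted(reg.associations_for(kind).items()):
                tinfo = reg.kind_info(assoc.target)
                areps = ["html", "xml", "json"]
                if tinfo.sequence_bearing:
                    areps.append("fasta")
                out.append(ResourceRoute(
                    f"/{info.plural}/{{id}}/{name}", kind, association=name,
                    cardinality=assoc.cardinality,
                    representations=tuple(areps)))
        return out

    # -- canonical URL construction -----------------------------------------

    def route_for(self, target, nested_under=None) -> str:
        """Canonical path of an entity, a collection, or a nested association.

        ``route_for(entity)`` -> member path;
        ``route_for("precursor")`` (a kind) -> collection path;
        ``route_for("precursors", nested_under=species)`` -> nested path.
        """
        if nested_under is not None:
            owner = self.route_for(nested_under)
            self.registry.association(nested_under.kind, target)
            return f"{owner}/{target}"
        if isinstance(target, str):
            info = self.registry.kind_info(target)
            return f"/{info.plural}"
        info = self.registry.kind_info(target.kind)
        return f"/{info.plural}/{encode_identifier(target.id)}"

    # -- request handling ----------------------------------------------------

    def resolve(self, method: str, path: str, accept: str = "",
                query: str = "") -> ResourceResponse:
        """Dispatch one request; every outcome is a status, never an exception."""
        if method.upper() != "GET":
            return _error(405, "read-only service: only GET is supported")

        path, fmt_suffix = _split_format(path)
        fmt = fmt_suffix or _format_from_accept(accept)
        params = {k: v[-1] for k, v in parse_qs(query).items()}

        segments = [unquote(s) for s in path.split("/") if s]

        if not segments:
            return self._index(fmt)
        if segments == ["described_routes"]:
            return self._described(fmt if fmt_suffix else "txt")

        info = None
        kind = self.registry.kind_for_plural(segments[0])
        if kind is None:
            return _error(404, f"unknown collection {segments[0]!r}")
        info = self.registry.kind_info(kind)

        if len(segments) == 1:
            entities = [self.dataset.store(kind)[i]
                        for i in sorted(self.dataset.store(kind))]
            return self._render_collection(info.plural, kind, entities,
                                           fmt, params)

        entity = self.dataset.store(kind).get(segments[1])
        if entity is None:
            return _error(404, f"no {kind} {segments[1]!r}")

        if len(segments) == 2:
            return self._render_member(entity, fmt)

        if len(segments) == 3:
            assoc_name = segments[2]
            try:
                assoc = self.registry.association(kind, assoc_name)
            except Exception:
                return _error(404, f"{kind} has no association "
                                   f"{assoc_name!r}")
            from .model import traverse
            result = traverse(entity, assoc_name)
            if assoc.cardinality == "one":
                if result is None:
                    return _error(404, f"{entity.id} has no {assoc_name}")
                return self._render_member(result, fmt)
            return self._render_collection(assoc_name, assoc.target, result,
                                           fmt, params)
        return _error(404, "no such resource")

    # -- renderers -----------------------------------------------------------

    def _render_member(self, entity, fmt: str) -> ResourceResponse:
        info = self.registry.kind_info(entity.kind)
        if fmt == "txt":
            return _error(406, "plain-text is only offered for "
                               "described_routes")
        if fmt == "fasta":
            if not info.sequence_bearing:
                return _error(406, f"{entity.kind} has no FASTA "
                                   f"representation")
            return _ok("fasta", render_fasta([entity]))
        if fmt == "xml":
            return _ok("xml", _xml_bytes(self.render_xml(entity)))
        if fmt == "json":
            return _ok("json", json.dumps(self._json_member(entity),
                                          indent=1).encode())
        return _ok("html", self._html_member(entity))

    def _render_collection(self, label, kind, entities, fmt,
                           params) -> ResourceResponse:
        info = self.registry.kind_info(kind)
        if fmt == "txt":
            return _error(406, "plain-text is only offered for "
                               "described_routes")
        try:
            entities = _paginate(entities, params)
        except ValueError as exc:
            return _error(404, str(exc))
        if fmt == "fasta":
            if not info.sequence_bearing:
                return _error(406, f"{kind} has no FASTA representation")
            return _ok("fasta", render_fasta(entities))
        if fmt == "xml":
            return _ok("xml", _xml_bytes(self.render_xml(entities,
                                                         label=label)))
        if fmt == "json":
            return _ok("json", json.dumps(
                [self._json_member(e) for e in entities], indent=1).encode())
        return _ok("html", self._html_collection(label, entities))

    def render_xml(self, target, label: Optional[str] = None):
        """XML element for an entity or a list of entities.

        Member documents carry one child element per model attribute plus a
        ``link`` element per association (the nested resource path, never an
        embedded object).  Lists get a plural root with a ``count``
        attribute.
        """
        if isinstance(target, list):
            root = ET.Element(label or "entities",
                              {"count": str(len(target))})
            for e in target:
                root.append(self.render_xml(e))
            return root
        info = self.registry.kind_info(target.kind)
        el = ET.Element(target.kind)
        for fname in info.fields:
            child = ET.SubElement(el, fname)
            child.text = str(getattr(target, fname))
        for name in self._advertised_associations(target.kind):
            ET.SubElement(el, "link", {
                "rel": name,
                "href": f"{self.route_for(target)}/{name}"})
        return el

    def _json_member(self, entity) -> dict:
        info = self.registry.kind_info(entity.kind)
        doc = {f: getattr(entity, f) for f in info.fields}
        doc["_links"] = {
            name: f"{self.route_for(entity)}/{name}"
            for name in self._advertised_associations(entity.kind)}
        return doc

    def _advertised_associations(self, kind: str) -> list:
        """Associations embedded in member documents.

        Plugin-contributed associations on *core* kinds are routable and
        listed in described_routes, but not embedded in core documents, so
        activating a plugin never changes a core response body.
        """
        info = self.registry.kind_info(kind)
        return sorted(
            name for name, assoc in
            self.registry.associations_for(kind).items()
            if assoc.origin in ("core", info.origin))

    def _html_member(self, entity) -> bytes:
        info = self.registry.kind_info(entity.kind)
        rows = "".join(
            f"<tr><th>{_html.escape(f)}</th>"
            f"<td>{_html.escape(str(getattr(entity, f)))}</td></tr>"
            for f in info.fields)
        links = "".join(
            f'<li><a href="{self.route_for(entity)}/{name}">'
            f"{_html.escape(name)}</a></li>"
            for name in self._advertised_associations(entity.kind))
        title = _html.escape(f"{entity.kind} {entity.id}")
        return (f"<!DOCTYPE html><html><head><title>{title}</title></head>"
                f"<body><h1>{title}</h1><table>{rows}</table>"
                f"<ul>{links}</ul></body></html>").encode()

    def _html_collection(self, label, entities) -> bytes:
        items = "".join(
            f'<li><a href="{self.route_for(e)}">'
            f"{_html.escape(str(e.id))}</a></li>" for e in entities)
        title = _html.escape(f"{label} ({len(entities)})")
        return (f"<!DOCTYPE html><html><head><title>{title}</title></head>"
                f"<body><h1>{title}</h1><ul>{items}</ul></body></html>"
                ).encode()

    def _index(self, fmt: str) -> ResourceResponse:
        links = "".join(
            f'<li><a href="/{info.plural}">{info.plural}</a></li>'
            for info in self.registry.kinds.values())
        body = (f"<!DOCTYPE html><html><head><title>mirhub</title></head>"
                f"<body><h1>mirhub release "
                f"{_html.escape(self.dataset.release_version)}</h1>"
                f"<ul>{links}</ul>"
                f'<p><a href="/described_routes.txt">described_routes</a>'
                f"</p></body></html>").encode()
        return _ok("html", body)

    # -- described routes ----------------------------------------------------

    def described_routes_text(self) -> str:
        lines = []
        for r in sorted(self.routes(), key=lambda r: r.path_template):
            lines.append(f"{r.path_template}\t"
                         f"[{','.join(r.representations)}]")
        return "\n".join(lines) + "\n"

    def described_routes_xml(self) -> bytes:
        root = ET.Element("described_routes")
        for r in sorted(self.routes(), key=lambda r: r.path_template):
            ET.SubElement(root, "route", {
                "path": r.path_template,
                "kind": r.kind,
                "association": r.association or "",
                "cardinality": r.cardinality,
                "representations": ",".join(r.representations)})
        return _xml_bytes(root)

    def _described(self, fmt: str) -> ResourceResponse:
        if fmt == "xml":
            return _ok("xml", self.described_routes_xml())
        return _ok("txt", self.described_routes_text().encode())


# ---------------------------------------------------------------------------
# Module-level renderers (usable without a Service)
# ---------------------------------------------------------------------------

def render_fasta(entities) -> bytes:
    """``>name accession`` headers, one line of sequence per record."""
    lines = []
    for e in entities:
        if not hasattr(e, "sequence"):
            raise TypeError(f"{e.kind} entities carry no sequence")
        lines.append(f">{e.id} {e.accession}")
        lines.append(e.sequence)
    return ("\n".join(lines) + "\n" if lines else "").encode()


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

_FORMAT_SUFFIX = re.compile(r"^(?P<stem>.*?)\.(?P<ext>html|xml|fasta|json|txt)$")


def _split_format(path: str):
    m = _FORMAT_SUFFIX.match(path)
    if m:
        return m.group("stem"), m.group("ext")
    return path, None


def _format_from_accept(accept: str) -> str:
    accept = accept or ""
    for token, fmt in _ACCEPT_TO_FORMAT:
        if token in accept:
            return fmt
    return "html"


def _paginate(entities, params):
    per_page = params.get("per_page", str(DEFAULT_PER_PAGE))
    if per_page == "all":
        return entities
    try:
        per_page_n = int(per_page)
        page = int(params.get("page", "1"))
    except ValueError as exc:
        raise ValueError(f"bad pagination parameter: {exc}") from exc
    if per_page_n < 1 or page < 1:
        raise ValueError("page and per_page must be >= 1")
    start = (page - 1) * per_page_n
    return entities[start:start + per_page_n]


def _ok(fmt: str, body: bytes) -> ResourceResponse:
    return ResourceResponse(200, MEDIA_TYPES[fmt], body)


def _error(status: int, message: str) -> ResourceResponse:
    body = (f"<!DOCTYPE html><html><body><h1>{status}</h1>"
            f"<p>{_html.escape(message)}</p></body></html>").encode()
    return ResourceResponse(status, MEDIA_TYPES["html"], body)


def _xml_bytes(el) -> bytes:
    return ET.tostring(el, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# WSGI
# ---------------------------------------------------------------------------

def wsgi_app(service: Service):
    """A minimal WSGI adapter over :meth:`Service.resolve`."""
    phrases = {200: "OK", 404: "Not Found", 405: "Method Not Allowed",
               406: "Not Acceptable"}

    def app(environ, start_response):
        resp = service.resolve(
            environ.get("REQUEST_METHOD", "GET"),
            environ.get("PATH_INFO", "/"),
            accept=environ.get("HTTP_ACCEPT", ""),
            query=environ.get("QUERY_STRING", ""))
        start_response(f"{resp.status} {phrases.get(resp.status, '')}",
                       [("Content-Type", resp.media_type),
                        ("Content-Length", str(len(resp.body)))])
        return [resp.body]

    return app


def serve(service: Service, host: str = "127.0.0.1", port: int = 8314):
    """Serve forever with the stdlib reference WSGI server."""
    from wsgiref.simple_server import make_server
    with make_server(host, port, wsgi_app(service)) as httpd:
        httpd.serve_forever()
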