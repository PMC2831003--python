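"""Uniform read-only resources: routing, negotiation, representations."""

import io
from xml.etree import ElementTree as ET

import pytest
from Bio import SeqIO

from mirhub.model import get_entity, list_entities
from mirhub.rest import Service


def parse_xml(resp):
    assert resp.status == 200 and resp.media_type.startswith(
        "application/xml")
    return ET.fromstring(resp.body)


class TestRouteFor:
    def test_member_path(self, full_service):
        prec = get_entity(full_service.dataset, "precursor", "zaa-mir-1")
        assert full_service.route_for(prec) == "/precursors/zaa-mir-1"

    def test_nested_collection_path(self, full_service):
        sp = get_entity(full_service.dataset, "species", "zaa")
        assert full_service.route_for("precursors", nested_under=sp) == \
            "/species/zaa/precursors"

    def test_papers_of_mature_path(self, full_service):
        m = get_entity(full_service.dataset, "mature", "zaa-miR-1")
        assert full_service.route_for("papers", nested_under=m) == \
            "/matures/zaa-miR-1/papers"

    def test_star_mature_keeps_literal_star(self, full_service):
        m = get_entity(full_service.dataset, "mature", "zaa-miR-1*")
        path = full_service.route_for(m)
        assert path == "/matures/zaa-miR-1*"
        assert full_service.resolve("GET", path + ".xml").status == 200


class TestResolve:
    def test_url_bijection_over_every_entity(self, full_service):
        ds = full_service.dataset
        seen_paths = set()
        for kind, store in ds.stores.items():
            id_field = ds.registry.kind_info(kind).id_field
            for entity in store.values():
                path = full_service.route_for(entity)
                assert path not in seen_paths
                seen_paths.add(path)
                doc = parse_xml(full_service.resolve("GET", path + ".xml"))
                assert doc.tag == kind
                assert doc.findtext(id_field) == str(entity.id)

    def test_xml_parse_back_recovers_all_attributes(self, full_service):
        ds = full_service.dataset
        for kind, store in ds.stores.items():
            info = ds.registry.kind_info(kind)
            for entity in store.values():
                doc = parse_xml(full_service.resolve(
                    "GET", full_service.route_for(entity) + ".xml"))
                for fname in info.fields:
                    assert (doc.findtext(fname) or "") == \
                        str(getattr(entity, fname))

    def test_cardinality_one_association_returns_member_document(
            self, full_service):
        doc = parse_xml(full_service.resolve(
            "GET", "/precursors/zaa-mir-1/species.xml"))
        assert doc.tag == "species"
        assert doc.findtext("abbreviation") == "zaa"

    def test_comment_attribute_via_xml(self, full_service):
        prec = get_entity(full_service.dataset, "precursor", "zab-mir-1")
        doc = parse_xml(full_service.resolve(
            "GET", "/precursors/zab-mir-1.xml"))
        assert doc.findtext("comment") == prec.comment

    def test_collection_has_count_and_members(self, full_service):
        doc = parse_xml(full_service.resolve("GET",
                                             "/precursors.xml",
                                             query="per_page=all"))
        n = len(full_service.dataset.store("precursor"))
        assert doc.get("count") == str(n) and len(doc) == n

    def test_empty_association_collection_count_zero(self, full_service):
        # precursor in the no-assembly species: no genome positions
        doc = parse_xml(full_service.resolve(
            "GET", "/precursors/zac-mir-1/genome_positions.xml"))
        assert doc.get("count") == "0" and len(doc) == 0

    def test_unknown_paths_404(self, full_service):
        for path in ("/genes", "/precursors/nope", "/precursors/zaa-mir-1/x",
                     "/precursors/zaa-mir-1/matures/too/deep"):
            assert full_service.resolve("GET", path).status == 404

    def test_non_get_is_405(self, full_service):
        for method in ("POST", "PUT", "DELETE", "PATCH"):
            assert full_service.resolve(
                method, "/precursors/zaa-mir-1").status == 405

    def test_read_only_fingerprint_unchanged_by_requests(self, full_service):
        ds = full_service.dataset
        before = ds.fingerprint()
        for path in ("/precursors.xml", "/species/zaa/matures.fasta",
                     "/matures/zaa-miR-1/papers.xml", "/nope",
                     "/precursors/zaa-mir-1.html", "/described_routes.txt"):
            full_service.resolve("GET", path)
        full_service.resolve("POST", "/precursors")
        assert ds.fingerprint() == before


class TestNegotiation:
    def test_accept_header_selects_xml(self, full_service):
        resp = full_service.resolve("GET", "/precursors/zaa-mir-1",
                                    accept="application/xml")
        assert resp.media_type.startswith("application/xml")

    def test_suffix_wins_over_accept(self, full_service):
        resp = full_service.resolve("GET", "/precursors/zaa-mir-1.xml",
                                    accept="text/html")
        assert resp.media_type.startswith("application/xml")

    def test_default_is_html(self, full_service):
        resp = full_service.resolve("GET", "/precursors/zaa-mir-1")
        assert resp.media_type.startswith("text/html")
        assert resp.body.lstrip().startswith(b"<!DOCTYPE html>")

    def test_fasta_unsupported_for_non_sequence_kind(self, full_service):
        assert full_service.resolve("GET", "/species/zaa.fasta").status == 406
        assert full_service.resolve("GET",
                                    "/seed_families.fasta").status == 406


class TestFasta:
    def test_single_precursor_record(self, full_service):
        resp = full_service.resolve("GET", "/precursors/zaa-mir-1.fasta")
        assert resp.status == 200
        assert resp.body.decode().startswith(">zaa-mir-1 ")

    def test_species_matures_parse_with_standard_reader(self, full_service):
        ds = full_service.dataset
        for sp in list_entities(ds, "species"):
            resp = full_service.resolve(
                "GET", f"/species/{sp.id}/matures.fasta",
                query="per_page=all")
            assert resp.status == 200
            records = list(SeqIO.parse(io.StringIO(resp.body.decode()),
                                       "fasta"))
            expected = len(ds.adjacency.get(("species", sp.id), {}))
            n_matures = len({m for p in ds.neighbors("species", sp.id,
                                                     "precursors")
                             for m in ds.neighbors("precursor", p,
                                                   "matures")})
            assert len(records) == n_matures
            for rec in records:
                assert rec.id in ds.store("mature")
                assert str(rec.seq) == ds.store("mature")[rec.id].sequence


class TestPagination:
    def test_concatenated_pages_equal_unpaginated(self, full_service):
        full = parse_xml(full_service.resolve("GET", "/matures.xml",
                                              query="per_page=all"))
        names = [el.findtext("name") for el in full]
        paged = []
        page = 1
        while True:
            doc = parse_xml(full_service.resolve(
                "GET", "/matures.xml", query=f"per_page=4&page={page}"))
            if len(doc) == 0:
                break
            paged.extend(el.findtext("name") for el in doc)
            page += 1
        assert paged == names


class TestDescribedRoutes:
    def test_core_templates_listed(self, full_service):
        text = full_service.described_routes_text()
        assert "/precursors\t" in text
        assert "/precursors/{id}\t" in text
        assert "/m2d_diseases/{id}\t" in text  # plugin routes included

    def test_listing_matches_router_template_set(self, full_service):
        listed = {line.split("\t")[0]
                  for line in
                  full_service.described_routes_text().splitlines()}
        assert listed == {r.path_template for r in full_service.routes()}
        doc = ET.fromstring(full_service.resolve(
            "GET", "/described_routes.xml").body)
        assert {el.get("path") for el in doc} == listed

    def test_every_listed_route_resolves_for_some_entity(self, full_service):
        ds = full_service.dataset
        for route in full_service.routes():
            if route.kind == "_meta":
                path = route.path_template
            else:
                store = ds.store(route.kind)
                if "{id}" in route.path_template:
                    fmt = route.representations[0]
                    resolved = False
                    for entity in store.values():
                        path = route.path_template.replace(
                            "{id}", full_service.route_for(entity)
                            .split("/")[-1])
                        if full_service.resolve(
                                "GET", f"{path}.{fmt}").status == 200:
                            resolved = True
                            break
                    assert resolved, f"no entity resolves {route}"
                    continue
                path = route.path_template
            assert full_service.resolve("GET", path).status == 200


class TestWsgi:
    def test_app_serves_resolve_output(self, full_service):
        from mirhub.rest import wsgi_app
        app = wsgi_app(full_service)
        captured = {}

        def start_response(status, headers):
            captured["status"] = status
            captured["headers"] = dict(headers)

        body = b"".join(app({"REQUEST_METHOD": "GET",
                             "PATH_INFO": "/precursors/zaa-mir-1.fasta"},
                            start_response))
        assert captured["status"].startswith("200")
        assert captured["headers"]["Content-Type"].startswith("text/plain")
        assert body.startswith(b">zaa-mir-1")
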