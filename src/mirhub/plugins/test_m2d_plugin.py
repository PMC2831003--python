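"""Self-contained test suite shipped by the disease plugin.

Run through the federated `selftest` command (or directly with pytest);
covers plugin models, resources and the connection to the core mature
model, against a generated fixture release.
"""

import pytest

from mirhub.fixtures import FixtureSpec, generate_release
from mirhub.ingest import build_dataset
from mirhub.model import get_entity, traverse
from mirhub.plugins import load_plugin_data, register_plugin
from mirhub.plugins.m2d import MANIFEST, link_identifier
from mirhub.rest import Service


@pytest.fixture(scope="module")
def plugin_dataset(tmp_path_factory):
    bundle, _ = generate_release(FixtureSpec(seed=7),
                                 tmp_path_factory.mktemp("rel"))
    ds = build_dataset(bundle)
    register_plugin(ds, MANIFEST)
    load_plugin_data(ds, MANIFEST)  # shipped synthetic tables
    return ds


def test_diseases_and_links_load(plugin_dataset):
    assert len(plugin_dataset.store("m2d_disease")) == 3
    assert len(plugin_dataset.store("m2d_disease_link")) == 5


def test_link_key_is_doid_mature_pubmed(plugin_dataset):
    ident = link_identifier("DOID:9000001", "zaa-miR-1", "99000001")
    link = get_entity(plugin_dataset, "m2d_disease_link", ident)
    assert (link.doid, link.mature_name, link.pubmed_id) == \
        ("DOID:9000001", "zaa-miR-1", "99000001")


def test_mature_to_links_traversal(plugin_dataset):
    mature = get_entity(plugin_dataset, "mature", "zaa-miR-1")
    links = traverse(mature, "m2d_disease_links")
    assert sorted(l.doid for l in links) == ["DOID:9000001", "DOID:9000002"]
    for link in links:
        assert traverse(link, "mature") is mature


def test_plugin_resources_resolve(plugin_dataset):
    svc = Service(plugin_dataset)
    assert svc.resolve("GET", "/m2d_diseases/DOID:9000001.xml").status == 200
    assert svc.resolve(
        "GET", "/matures/zaa-miR-1/m2d_disease_links.xml").status == 200
    assert "/m2d_diseases/{id}" in svc.described_routes_text()
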