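"""Extend the core with a plugin: disease annotations on mature miRNAs.

The shipped example plugin declares two new kinds (diseases keyed by DOID,
disease links keyed by DOID+mature+PubMed), a one-many association to the
core mature model, a loader for its tab-delimited tables, and its own test
file.  Registration never changes core responses — plugins only add.
"""

from tempfile import TemporaryDirectory

from mirhub import (FixtureSpec, Service, build_dataset, generate_release,
                    get_entity, load_plugin_data, register_plugin, traverse)
from mirhub.plugins.m2d import MANIFEST

with TemporaryDirectory() as tmp:
    bundle, _ = generate_release(FixtureSpec(seed=42), tmp)
    ds = build_dataset(bundle)

    register_plugin(ds, MANIFEST)
    n = load_plugin_data(ds, MANIFEST)  # shipped synthetic tables
    print(f"loaded {n} plugin entities")

    mature = get_entity(ds, "mature", "zaa-miR-1")
    for link in traverse(mature, "m2d_disease_links"):
        disease = traverse(link, "m2d_disease")
        print(f"  {mature.name} -> {disease.name} "
              f"[{link.doid}, PMID {link.pubmed_id}, "
              f"targets {link.target_genes}]")

    svc = Service(ds)
    print("disease URL status:",
          svc.resolve("GET", "/m2d_diseases/DOID:9000001.xml").status)
    print("nested link route:",
          svc.resolve("GET",
                      "/matures/zaa-miR-1/m2d_disease_links.xml").status)
    print("plugin routes listed:",
          "/m2d_diseases/{id}" in svc.described_routes_text())

# Expected: 8 entities (3 diseases + 5 links); zaa-miR-1 is linked to two
# synthetic diseases; the plugin's member and nested routes resolve and are
# advertised by described_routes.
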