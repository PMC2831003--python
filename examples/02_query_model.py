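"""Query the object model directly: lookup, listing, association traversal.

Mirrors the typical interactive session: fetch a hairpin by name, walk to
its matures, species and literature, and filter collections.
"""

from tempfile import TemporaryDirectory

from mirhub import (FixtureSpec, Window, build_dataset, generate_release,
                    get_entity, list_entities, traverse)

with TemporaryDirectory() as tmp:
    bundle, _ = generate_release(FixtureSpec(seed=42), tmp)
    ds = build_dataset(bundle)

    hairpin = get_entity(ds, "precursor", "zaa-mir-1")
    print("hairpin:", hairpin.name, hairpin.accession,
          f"({len(hairpin.sequence)} nt)")

    # a hairpin yields its guide and star strands; the star carries '*'
    for mature in traverse(hairpin, "matures"):
        print("  mature:", mature.name, mature.accession, mature.sequence)

    print("species:", traverse(hairpin, "species").name)

    # literature is attached to hairpin records; a mature inherits the
    # deduplicated union over all hairpins it derives from
    mature = get_entity(ds, "mature", "zaa-miR-3")
    print("papers via", mature.name, ":",
          [p.medline for p in traverse(mature, "papers")])

    # deterministic, filterable, window-paged listings
    zab = list_entities(ds, "precursor",
                        filter=lambda p: traverse(p, "species").id == "zab")
    print("zab precursors:", [p.name for p in zab])
    print("first two matures:",
          [m.name for m in list_entities(ds, "mature",
                                         window=Window(0, 2))])

# Expected: zaa-mir-1 carries zaa-miR-1 and zaa-miR-1*; zaa-miR-3 is shared
# by two hairpins, so its paper list unions both hairpins' references.
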