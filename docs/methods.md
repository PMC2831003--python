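# Methods

## The data model

One release is modelled as a closed universe (`Dataset`) of nine entity
kinds. Entities live in insertion-ordered stores keyed by a canonical
identifier: the miRBase-style *name* for species, precursors, matures,
precursor families, clusters and seed families; the PubMed id for papers;
and a synthetic stable id (`<precursor>-pos-<n>` / `<precursor>-ctx-<n>`)
for genome positions and contexts, which the source files leave anonymous
but which must be addressable as web resources. Lookup is case-sensitive:
`hsa-mir-21` (hairpin) and `hsa-miR-21` (mature) are different names in
different namespaces, and case-folding would invite silent aliasing.

Associations are stored as adjacency lists in both directions, so traversal
is symmetric by construction and an integrity validator can check the edge
set mechanically. Three associations are *computed* rather than stored:
literature attaches to hairpin records, so a mature's papers are defined as
the deduplicated union over its linked hairpins (and symmetrically
paper→matures, species→matures). 'Many' traversals return lists sorted by
canonical identifier; all listings are deterministic and windowable, so
pagination is stable.

Sequences are stored as uppercase RNA; `T` is normalized to `U` at ingest
because releases mix DNA- and RNA-alphabet dumps. A hairpin without genome
coordinates is legal — not every species has an assembly.

`validate_dataset` reports violations as data rather than raising: unique
accession shape (`MI\d+` / `MIMAT\d+`), the species prefix rule, the
substring law (every mature sequence occurs in every linked hairpin),
interval sanity, orphan detection, at-most-one curated family/cluster per
precursor, and edge referential integrity/symmetry.

## Ingest

The hairpin record file is the only mandatory bundle member; the family
file, per-species GFFs, FASTA pair and the two tab dumps (species table,
genome-context table) degrade gracefully when absent. The context and
species dumps have no published flat-file layout, so this package fixes a
five-column tab dialect of its own and the fixture generator emits it; the
GFF parser accepts both the quoted attribute dialect (`ACC="MI…";
ID="name";`) and GFF3 `ID=`/`Name=` attributes, and preserves 1-based
inclusive coordinates verbatim.

The defect policy is *skip and log*: malformed records or lines (including
mature features whose coordinates fall outside the hairpin) are dropped
with a logged reason and never abort ingest; only a missing hairpin file is
fatal. Real releases contain oddities and ingest must be total. Where the
hairpin/mature FASTA disagrees with a record, the record file wins and the
disagreement is logged. Comment (CC) lines join with single spaces;
reference author lines join with `", "`. Matures are deduplicated by
accession across hairpins, which establishes the precursor↔mature
many-to-many.

The EMBL-dialect and GFF parsers are hand-written because the per-record
skip+log contract with line numbers drives the design; the generated
records remain standard enough that Biopython's EMBL reader parses them,
and the test suite uses that second, independent route (plus `Bio.SeqIO`
FASTA parsing) as a cross-check on names, sequences and feature
coordinates.

## Derived groupings

**Seed families.** The seed of a mature is bases 2–7 (6mer) or 2–8 (7mer),
1-based. For each k the matures of length ≥ k+1 are partitioned by seed;
the family's name *is* the seed sequence (collision-free,
self-describing). Both k=6 and k=7 family sets are materialized side by
side, distinguished by sequence length, since either convention is in use;
too-short matures stay unassigned and are logged. Re-derivation replaces
only the families of the requested length (idempotent).

**Precursor clusters.** Two hairpins are adjacent when they have placements
on the same chromosome — and the same strand under the default
`same_strand_required=True`, since "presumably co-transcribed" implies one
polycistronic transcript — whose interval-hull gap
`max(start₁,start₂) − min(end₁,end₂)`, floored at 0 for overlaps, is at
most `max_gap`. Clusters are the single-linkage connected components of
size ≥ 2, computed exactly by a start-sorted sweep that links an interval
to the running component while the gap to its rightmost end is within
`max_gap` (a precursor with placements in several groups bridges them via
union-find). The default `max_gap` is 10 000 nt, the conventional miRNA
polycistron window; the threshold is a declared package default, not a
recovered constant, and is configurable per call, as is the strand rule.
Components are named `<species>-cluster-<xsome>-<ordinal>` ordered by
leftmost start, so output is reproducible. A test-suite oracle (O(n²)
pairwise adjacency + networkx transitive closure) confirms exactness, and a
ladder test confirms the partition coarsens monotonically in `max_gap`.

The `neighborhood` query returns all hairpins with a placement overlapping
`[start−w, end+w]` of any placement of the query on the same chromosome,
strand-blind (a nearby antisense hairpin is still a neighbour), ordered by
start.

## REST layer

Member URLs are `/<plural>/<id>`, collections `/<plural>`, associations
`/<plural>/<id>/<association>`; identifiers are percent-encoded with `*`
kept literal (star strands stay readable). Negotiation: path suffix
(`.xml`, `.fasta`, `.html`, `.json`) wins, Accept header is the fallback,
HTML the default. FASTA is offered only for sequence-bearing kinds
(precursors, matures) and collections/associations targeting them; asking
elsewhere yields 406. Non-GET verbs yield 405 — the resources are strictly
read-only, and a content fingerprint over all stores and edges proves no
request sequence mutates the dataset. Collections paginate via
`page`/`per_page` (default 100, `per_page=all` for unbounded dumps). XML
member documents carry one child element per model attribute and `link`
elements holding nested resource paths, never embedded objects, so the
schema is stable across releases. `/described_routes.txt` (and `.xml`)
lists every registered template with its representations, plugins included.

The web layer is a small WSGI application on the standard library; any WSGI
container can host it, and `mirhub serve` uses the stdlib reference server.

## Plugins

A plugin is a declarative manifest: new types (kind, plural, id field,
fields), associations to existing kinds with explicit inverses, a loader
callable, and a pytest file (manifests without tests are rejected).
Registration is collision-checked (kinds, plurals, association names) and
rejects associations to unknown kinds. Load order is alphabetical and
asserted not to matter. Plugin entities are generated dataclasses, so they
flow through lookup, traversal, validation, snapshots and REST like core
entities.

Isolation is a hard guarantee: plugin-contributed associations on core
kinds are routable and listed in `described_routes`, but are *not*
embedded as links in core member documents, so every core-route response is
byte-identical with and without plugins. Overriding core representations is
deliberately impossible.

The shipped example plugin models disease annotations: diseases keyed by a
Disease Ontology id and links keyed by `DOID+mature+PubMed`, one-many from
matures. Its data files are synthetic (flagged in their filenames) and
exist to exercise the mechanics, not to mirror any real disease resource.

## Synthetic releases and what the tests show

The fixture generator emulates one release at desk scale: by default 3
species × 5 hairpins (60–120 nt, uniform base composition patched to embed
the planted structure), 1–2 matures per hairpin (20–24 nt; 22 nt default),
star strands on alternate hairpins, one mature shared verbatim between two
hairpins per species, per-species literature with one shared reference,
two curated families, one species without an assembly, a hairpin with two
genome placements, inter-hairpin gaps of 720 nt, exactly `max_gap`, and
`max_gap`+1 bracketing the clustering threshold, two matures per species
sharing a 7mer seed, and optionally one 7 nt mature (6mer-eligible,
7mer-ineligible). All draws come from one seeded RNG and iteration is
insertion-ordered, so output is byte-identical per seed. The manifest's
expected groupings are computed from the *plan* (planted gaps and seeds),
never by running the clustering or grouping code.

What passing tests do **not** show about real releases: the generator does
not emulate hairpin secondary structure, biological base composition,
conservation, the scale of a full release (tens of thousands of records),
nor its historical format quirks beyond the dialects described above. The
skip-and-log policy is exercised with constructed defects, not with the
long tail of real-world oddities. Release-scale figures (hundreds of
species, >10⁴ hairpins) therefore require running ingest on a downloaded
release via `mirhub fetch`; nothing in the test suite or acceptance script
touches the network.

Problem sizes in the acceptance script — 20 round-trip seeds at the default
fixture scale, 200 positions for the cluster oracle (500 in the test
suite), a full crawl of every fixture entity in XML — were chosen as the
smallest instances that exercise every planted edge case and both sides of
each oracle.

## Numerical / procedural choices

* Gap arithmetic is integer, on 1-based inclusive intervals; book-ended
  intervals (`start₂ = end₁ + 1`) have gap 1, overlapping/nested pairs gap 0.
* Ties in cluster and neighborhood ordering break lexicographically by
  name; family iteration is sorted by seed sequence — all outputs are
  deterministic given the dataset.
* `Window(offset, limit)` slices after sorting; an empty window is legal
  and yields an empty list.
* Dataset snapshots are plain JSON (entities plus adjacency), with the
  registry (core + requested plugins) reconstructing entity classes on
  load.

## Known limitations

* The in-memory model targets release-scale data comfortably but offers no
  concurrent-writer story; it is a read-only snapshot by design.
* `fetch_release` covers the four principal archive members; per-species
  coordinate files must currently be fetched by hand because the archive
  layout is not enumerable without listing support.
* Mature names are assumed unique release-wide (they key the store); a
  release that reuses a name under a second accession logs the collision
  and keeps the first record.
* The HTML representation is deliberately minimal — an attribute table and
  association links — and is not meant as a browsing product.
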