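"""Core data model: entity types, the Dataset container, lookup and traversal.

The model mirrors the relational universe of one miRBase-style release:
hairpin precursors, mature miRNAs, species, curated precursor families,
genomic placements and contexts, literature references, plus two *derived*
groupings (seed families and genomic precursor clusters) that are computed
rather than read from files.

Entities live in per-kind stores keyed by a canonical identifier (the
miRBase name for sequence-bearing kinds, the PubMed id for papers, a
synthetic stable id for positions/contexts).  Associations are stored as
adjacency lists in both directions; a few associations (mature <-> papers)
are *computed* on the fly as the deduplicated union over linked precursors,
because the literature is attached to hairpin records.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Iterable, Optional

from .errors import NotFoundError, UnknownAssociationError, UnknownKindError

RNA_ALPHABET = set("ACGUN")

MI_ACCESSION = re.compile(r"^MI\d+$")
MIMAT_ACCESSION = re.compile(r"^MIMAT\d+$")


# ---------------------------------------------------------------------------
# Entity types
# ---------------------------------------------------------------------------

@dataclass
class Species:
    """A taxonomic species with miRNAs encoded in its genome."""

    abbreviation: str
    name: str
    division: str = ""
    taxonomy: str = ""
    genome_assembly: str = ""

    kind = "species"

    @property
    def id(self) -> str:
        return self.abbreviation


@dataclass
class Precursor:
    """A hairpin precursor, processed from a longer primary transcript."""

    name: str
    accession: str
    description: str = ""
    sequence: str = ""
    comment: str = ""

    kind = "precursor"

    @property
    def id(self) -> str:
        return self.name


@dataclass
class Mature:
    """A mature miRNA excised from one or more hairpin precursors."""

    name: str
    accession: str
    evidence: str = ""
    experiment: str = ""
    similarity: str = ""
    sequence: str = ""

    kind = "mature"

    @property
    def id(self) -> str:
        return self.name


@dataclass
class PrecursorFamily:
    """The curated miRBase grouping of evolutionarily related hairpins."""

    name: str
    accession: str = ""
    description: str = ""

    kind = "precursor_family"

    @property
    def id(self) -> str:
        return self.name


@dataclass
class GenomePosition:
    """One genomic placement of a precursor (1-based, inclusive)."""

    identifier: str
    xsome: str
    contig_start: int
    contig_end: int
    strand: str

    kind = "genome_position"

    @property
    def id(self) -> str:
        return self.identifier


@dataclass
class GenomeContext:
    """An overlapping gene-model annotation for a precursor locus."""

    identifier: str
    overlap_sense: str
    overlap_type: str
    transcript_source: str
    transcript_name: str

    kind = "genome_context"

    @property
    def id(self) -> str:
        return self.identifier


@dataclass
class PrecursorCluster:
    """Genomically proximal precursors, presumably one polycistron. Derived."""

    name: str

    kind = "precursor_cluster"

    @property
    def id(self) -> str:
        return self.name


@dataclass
class SeedFamily:
    """Mature miRNAs sharing a 6mer (bases 2-7) or 7mer (bases 2-8) seed.

    Derived, never read from input files; the name *is* the seed sequence.
    """

    name: str
    sequence: str = ""

    kind = "seed_family"

    def __post_init__(self):
        if not self.sequence:
            self.sequence = self.name

    @property
    def id(self) -> str:
        return self.name


@dataclass
class Paper:
    """A literature reference attached to one or more hairpin records."""

    medline: str
    title: str = ""
    author: str = ""
    journal: str = ""

    kind = "paper"

    @property
    def id(self) -> str:
        return self.medline


CORE_ENTITY_CLASSES = (
    Species, Precursor, Mature, PrecursorFamily, GenomePosition,
    GenomeContext, PrecursorCluster, SeedFamily, Paper,
)


# ---------------------------------------------------------------------------
# Kind / association registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KindInfo:
    """Static description of an entity kind used by lookup and rendering."""

    kind: str
    plural: str
    id_field: str
    fields: tuple
    sequence_bearing: bool = False
    factory: Optional[Callable] = None
    origin: str = "core"


@dataclass(frozen=True)
class Association:
    """A named, directed association; `inverse` names the reverse direction."""

    source: str
    name: str
    target: str
    cardinality: str  # 'one' | 'many'
    inverse: Optional[str] = None
    resolver: Optional[Callable] = None  # computed association: f(ds, entity) -> [ids]
    origin: str = "core"  # which registration introduced it (core | plugin name)


def _mature_papers(ds: "Dataset", mature: Mature) -> list:
    seen, out = set(), []
    for pname in ds.neighbors("mature", mature.id, "precursors"):
        for medline in ds.neighbors("precursor", pname, "papers"):
            if medline not in seen:
                seen.add(medline)
                out.append(medline)
    return sorted(out)


def _species_matures(ds: "Dataset", sp: Species) -> list:
    seen, out = set(), []
    for pname in ds.neighbors("species", sp.id, "precursors"):
        for mname in ds.neighbors("precursor", pname, "matures"):
            if mname not in seen:
                seen.add(mname)
                out.append(mname)
    return sorted(out)


def _mature_species(ds: "Dataset", mature: Mature) -> list:
    out = set()
    for pname in ds.neighbors("mature", mature.id, "precursors"):
        out.update(ds.neighbors("precursor", pname, "species"))
    return sorted(out)


def _paper_matures(ds: "Dataset", paper: Paper) -> list:
    seen, out = set(), []
    for pname in ds.neighbors("paper", paper.medline, "precursors"):
        for mname in ds.neighbors("precursor", pname, "matures"):
            if mname not in seen:
                seen.add(mname)
                out.append(mname)
    return sorted(out)


class Registry:
    """Registry of entity kinds and associations (core plus plugins)."""

    def __init__(self):
        self.kinds: dict[str, KindInfo] = {}
        self.associations: dict[tuple, Association] = {}

    def register_kind(self, info: KindInfo) -> None:
        if info.kind in self.kinds:
            raise ValueError(f"kind {info.kind!r} already registered")
        if any(k.plural == info.plural for k in self.kinds.values()):
            raise ValueError(f"plural {info.plural!r} already registered")
        self.kinds[info.kind] = info

    def register_association(self, assoc: Association) -> None:
        key = (assoc.source, assoc.name)
        if key in self.associations:
            raise ValueError(f"association {key} already registered")
        self.associations[key] = assoc

    def kind_info(self, kind: str) -> KindInfo:
        try:
            return self.kinds[kind]
        except KeyError:
            raise UnknownKindError(kind, self.kinds) from None

    def kind_for_plural(self, plural: str) -> Optional[str]:
        for info in self.kinds.values():
            if info.plural == plural:
                return info.kind
        return None

    def association(self, kind: str, name: str) -> Association:
        try:
            return self.associations[(kind, name)]
        except KeyError:
            valid = [n for (k, n) in self.associations if k == kind]
            raise UnknownAssociationError(kind, name, valid) from None

    def associations_for(self, kind: str) -> dict:
        return {n: a for (k, n), a in self.associations.items() if k == kind}


def core_registry() -> Registry:
    """A fresh registry holding the nine core kinds and their associations."""
    reg = Registry()
    reg.register_kind(KindInfo("species", "species", "abbreviation",
                               ("abbreviation", "name", "division", "taxonomy",
                                "genome_assembly"), factory=Species))
    reg.register_kind(KindInfo("precursor", "precursors", "name",
                               ("name", "accession", "description", "sequence",
                                "comment"), sequence_bearing=True,
                               factory=Precursor))
    reg.register_kind(KindInfo("mature", "matures", "name",
                               ("name", "accession", "evidence", "experiment",
                                "similarity", "sequence"),
                               sequence_bearing=True, factory=Mature))
    reg.register_kind(KindInfo("precursor_family", "precursor_families", "name",
                               ("name", "accession", "description"),
                               factory=PrecursorFamily))
    reg.register_kind(KindInfo("genome_position", "genome_positions",
                               "identifier",
                               ("identifier", "xsome", "contig_start",
                                "contig_end", "strand"),
                               factory=GenomePosition))
    reg.register_kind(KindInfo("genome_context", "genome_contexts",
                               "identifier",
                               ("identifier", "overlap_sense", "overlap_type",
                                "transcript_source", "transcript_name"),
                               factory=GenomeContext))
    reg.register_kind(KindInfo("precursor_cluster", "precursor_clusters",
                               "name", ("name",), factory=PrecursorCluster))
    reg.register_kind(KindInfo("seed_family", "seed_families", "name",
                               ("name", "sequence"), factory=SeedFamily))
    reg.register_kind(KindInfo("paper", "papers", "medline",
                               ("medline", "title", "author", "journal"),
                               factory=Paper))

    pairs = [
        # (source, name, target, cardinality, inverse-name, inverse-cardinality)
        ("species", "precursors", "precursor", "many", "species", "one"),
        ("precursor", "matures", "mature", "many", "precursors", "many"),
        ("precursor", "papers", "paper", "many", "precursors", "many"),
        ("precursor", "genome_positions", "genome_position", "many",
         "precursor", "one"),
        ("precursor", "genome_contexts", "genome_context", "many",
         "precursor", "one"),
        ("precursor_family", "precursors", "precursor", "many",
         "precursor_family", "one"),
        ("precursor_cluster", "precursors", "precursor", "many",
         "precursor_cluster", "one"),
        ("seed_family", "matures", "mature", "many", "seed_families", "many"),
    ]
    for src, name, tgt, card, inv, inv_card in pairs:
        reg.register_association(Association(src, name, tgt, card, inverse=inv))
        reg.register_association(Association(tgt, inv, src, inv_card,
                                             inverse=name))
    # computed: literature attaches to hairpins; matures inherit the union
    reg.register_association(Association("mature", "papers", "paper", "many",
                                         inverse="matures",
                                         resolver=_mature_papers))
    reg.register_association(Association("paper", "matures", "mature", "many",
                                         inverse="papers",
                                         resolver=_paper_matures))
    # matures attach to a species through their hairpins
    reg.register_association(Association("species", "matures", "mature",
                                         "many", inverse="species",
                                         resolver=_species_matures))
    reg.register_association(Association("mature", "species", "species",
                                         "one", inverse="matures",
                                         resolver=_mature_species))
    return reg


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Window:
    """A slice applied after deterministic ordering: offset + limit."""

    offset: int = 0
    limit: Optional[int] = None


class Dataset:
    """The in-memory universe of one ingested release.

    Stores are insertion-ordered dicts keyed by canonical identifier;
    adjacency lists hold every stored association in both directions, so
    traversal is symmetric by construction.
    """

    def __init__(self, release_version: str = "", registry: Registry = None):
        self.release_version = release_version
        self.registry = registry or core_registry()
        self.stores: dict[str, dict] = {k: {} for k in self.registry.kinds}
        self.adjacency: dict[tuple, dict] = {}

    # -- construction ------------------------------------------------------

    def add(self, entity) -> None:
        kind = entity.kind
        if kind not in self.stores:
            if kind not in self.registry.kinds:
                raise UnknownKindError(kind, self.registry.kinds)
            self.stores[kind] = {}
        store = self.stores[kind]
        if entity.id in store:
            raise ValueError(f"duplicate {kind} identifier {entity.id!r}")
        store[entity.id] = entity
        entity._dataset = self

    def link(self, source_kind: str, source_id: str, association: str,
             target_id: str) -> None:
        """Record an association edge in both directions."""
        assoc = self.registry.association(source_kind, association)
        if assoc.resolver is not None:
            raise ValueError(f"association {association!r} is computed")
        self._edge(source_kind, association, source_id, target_id)
        if assoc.inverse is not None:
            self._edge(assoc.target, assoc.inverse, target_id, source_id)

    def remove_entity(self, kind: str, identifier: str) -> None:
        """Delete one entity and every edge that references it."""
        self.stores[kind].pop(identifier, None)
        for (k, name), adj in list(self.adjacency.items()):
            assoc = self.registry.associations.get((k, name))
            if k == kind:
                adj.pop(identifier, None)
            if assoc and assoc.target == kind:
                for sid in list(adj):
                    adj[sid] = [t for t in adj[sid] if t != identifier]
                    if not adj[sid]:
                        del adj[sid]

    def unlink_kind(self, kind: str) -> None:
        """Drop every entity of `kind` and all edges touching it (rerun support)."""
        for (k, name), adj in list(self.adjacency.items()):
            assoc = self.registry.associations.get((k, name))
            if k == kind or (assoc and assoc.target == kind):
                del self.adjacency[(k, name)]
        self.stores[kind] = {}

    def _edge(self, kind, name, source_id, target_id):
        adj = self.adjacency.setdefault((kind, name), {})
        lst = adj.setdefault(source_id, [])
        if target_id not in lst:
            lst.append(target_id)

    # -- access ------------------------------------------------------------

    def store(self, kind: str) -> dict:
        if kind not in self.registry.kinds:
            raise UnknownKindError(kind, self.registry.kinds)
        return self.stores.setdefault(kind, {})

    def neighbors(self, kind: str, identifier: str, association: str) -> list:
        """Sorted target identifiers of a stored association."""
        return sorted(self.adjacency.get((kind, association), {})
                      .get(identifier, []))

    def fingerprint(self) -> str:
        """Content hash over all entities and edges; used to prove read-only."""
        payload = {
            "release_version": self.release_version,
            "stores": {
                kind: {eid: _entity_dict(e) for eid, e in sorted(store.items())}
                for kind, store in sorted(self.stores.items())
            },
            "adjacency": {
                f"{k}:{n}": {s: sorted(t) for s, t in sorted(adj.items())}
                for (k, n), adj in sorted(self.adjacency.items())
            },
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "release_version": self.release_version,
            "stores": {
                kind: [_entity_dict(e) for e in store.values()]
                for kind, store in self.stores.items()
            },
            "adjacency": {
                f"{kind}\t{name}": adj
                for (kind, name), adj in self.adjacency.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str, registry: Registry = None) -> "Dataset":
        payload = json.loads(text)
        ds = cls(payload.get("release_version", ""), registry=registry)
        for kind, rows in payload["stores"].items():
            info = ds.registry.kind_info(kind)
            for row in rows:
                ds.add(info.factory(**row))
        for key, adj in payload["adjacency"].items():
            kind, name = key.split("\t")
            ds.adjacency[(kind, name)] = {s: list(t) for s, t in adj.items()}
        return ds


def _entity_dict(entity) -> dict:
    return {f.name: getattr(entity, f.name) for f in dc_fields(entity)}


# ---------------------------------------------------------------------------
# Query operations
# ---------------------------------------------------------------------------

def get_entity(dataset: Dataset, kind: str, identifier: str):
    """Case-sensitive lookup of an entity by its canonical identifier."""
    store = dataset.store(kind)
    try:
        return store[identifier]
    except KeyError:
        raise NotFoundError(kind, identifier) from None


def list_entities(dataset: Dataset, kind: str,
                  filter: Optional[Callable] = None,
                  window: Optional[Window] = None) -> list:
    """All entities of `kind` in lexicographic identifier order.

    `filter` restricts (a predicate over entities); `window` slices after
    ordering, so pagination is stable.
    """
    store = dataset.store(kind)
    out = [store[i] for i in sorted(store)]
    if filter is not None:
        out = [e for e in out if filter(e)]
    if window is not None:
        if isinstance(window, tuple):
            window = Window(*window)
        stop = None if window.limit is None else window.offset + window.limit
        out = out[window.offset:stop]
    return out


def traverse(entity, association: str):
    """Follow a named association from an entity.

    'one' associations return the single target entity or None; 'many'
    associations return a list sorted by canonical identifier.
    """
    ds: Dataset = entity._dataset
    assoc = ds.registry.association(entity.kind, association)
    if assoc.resolver is not None:
        ids = assoc.resolver(ds, entity)
    else:
        ids = ds.neighbors(entity.kind, entity.id, association)
    target_store = ds.store(assoc.target)
    if assoc.cardinality == "one":
        return target_store[ids[0]] if ids else None
    return [target_store[i] for i in ids if i in target_store]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    rule: str
    kind: str
    identifier: str
    message: str


def validate_dataset(dataset: Dataset) -> list:
    """Runtime integrity check: one Violation per broken invariant.

    An empty report means every core-model invariant holds.  Violations are
    data, not exceptions: a defective dataset is still inspectable.
    """
    v: list[Violation] = []
    ds = dataset

    def seen_dupes(kind, attr):
        seen = {}
        for e in ds.store(kind).values():
            val = getattr(e, attr)
            if val in seen:
                v.append(Violation(f"{kind}.{attr}.unique", kind, e.id,
                                   f"{attr} {val!r} also used by "
                                   f"{seen[val]!r}"))
            else:
                seen[val] = e.id

    seen_dupes("precursor", "accession")
    seen_dupes("mature", "accession")
    seen_dupes("precursor_family", "name")

    for sp in ds.store("species").values():
        if not sp.abbreviation:
            v.append(Violation("species.abbreviation.nonempty", "species",
                               sp.id, "empty abbreviation"))
        for pname in ds.neighbors("species", sp.id, "precursors"):
            if not pname.startswith(sp.abbreviation + "-"):
                v.append(Violation("species.prefix", "precursor", pname,
                                   f"name does not start with "
                                   f"{sp.abbreviation!r}-"))

    for p in ds.store("precursor").values():
        if not p.sequence:
            v.append(Violation("precursor.sequence.nonempty", "precursor",
                               p.id, "empty sequence"))
        elif not set(p.sequence) <= RNA_ALPHABET:
            v.append(Violation("precursor.sequence.alphabet", "precursor",
                               p.id, "non-RNA characters in sequence"))
        if not MI_ACCESSION.match(p.accession):
            v.append(Violation("precursor.accession.shape", "precursor",
                               p.id, f"accession {p.accession!r} not MI-shaped"))
        if len(ds.neighbors("precursor", p.id, "species")) != 1:
            v.append(Violation("precursor.species.one", "precursor", p.id,
                               "not linked to exactly one species"))
        for grouping in ("precursor_family", "precursor_cluster"):
            if len(ds.neighbors("precursor", p.id, grouping)) > 1:
                v.append(Violation(f"precursor.{grouping}.at_most_one",
                                   "precursor", p.id,
                                   f"member of several {grouping} groups"))

    for m in ds.store("mature").values():
        if not MIMAT_ACCESSION.match(m.accession):
            v.append(Violation("mature.accession.shape", "mature", m.id,
                               f"accession {m.accession!r} not MIMAT-shaped"))
        precs = ds.neighbors("mature", m.id, "precursors")
        if not precs:
            v.append(Violation("mature.orphan", "mature", m.id,
                               "linked to no precursor"))
        for pname in precs:
            prec = ds.store("precursor").get(pname)
            if prec is not None and m.sequence not in prec.sequence:
                v.append(Violation("mature.substring", "mature", m.id,
                                   f"sequence not a substring of {pname!r}"))

    for gp in ds.store("genome_position").values():
        if not (1 <= gp.contig_start <= gp.contig_end):
            v.append(Violation("genome_position.bounds", "genome_position",
                               gp.id, f"bad interval "
                               f"[{gp.contig_start},{gp.contig_end}]"))
        if gp.strand not in ("+", "-"):
            v.append(Violation("genome_position.strand", "genome_position",
                               gp.id, f"strand {gp.strand!r}"))
        if len(ds.neighbors("genome_position", gp.id, "precursor")) != 1:
            v.append(Violation("genome_position.orphan", "genome_position",
                               gp.id, "not linked to exactly one precursor"))

    for gc in ds.store("genome_context").values():
        if gc.overlap_sense not in ("sense", "antisense", "unknown"):
            v.append(Violation("genome_context.sense", "genome_context",
                               gc.id, f"overlap_sense {gc.overlap_sense!r}"))
        if len(ds.neighbors("genome_context", gc.id, "precursor")) != 1:
            v.append(Violation("genome_context.orphan", "genome_context",
                               gc.id, "not linked to exactly one precursor"))

    for fam in ds.store("precursor_family").values():
        if not ds.neighbors("precursor_family", fam.id, "precursors"):
            v.append(Violation("precursor_family.nonempty", "precursor_family",
                               fam.id, "no member precursors"))

    for cl in ds.store("precursor_cluster").values():
        if not ds.neighbors("precursor_cluster", cl.id, "precursors"):
            v.append(Violation("precursor_cluster.nonempty",
                               "precursor_cluster", cl.id, "no members"))

    for sf in ds.store("seed_family").values():
        k = len(sf.sequence)
        if k not in (6, 7):
            v.append(Violation("seed_family.length", "seed_family", sf.id,
                               f"seed length {k}"))
        for mname in ds.neighbors("seed_family", sf.id, "matures"):
            m = ds.store("mature").get(mname)
            if m is not None and m.sequence[1:1 + k] != sf.sequence:
                v.append(Violation("seed_family.member_seed", "seed_family",
                                   sf.id, f"member {mname!r} seed mismatch"))

    for pap in ds.store("paper").values():
        if not ds.neighbors("paper", pap.id, "precursors"):
            v.append(Violation("paper.orphan", "paper", pap.id,
                               "linked to no precursor"))

    # referential integrity + inverse symmetry over stored edges
    for (kind, name), adj in ds.adjacency.items():
        assoc = ds.registry.associations.get((kind, name))
        if assoc is None:
            v.append(Violation("association.undeclared", kind, name,
                               "edges for an undeclared association"))
            continue
        src_store = ds.store(kind)
        tgt_store = ds.store(assoc.target)
        for sid, tids in adj.items():
            if sid not in src_store:
                v.append(Violation("association.dangling_source", kind, sid,
                                   f"edge source missing for {name!r}"))
            for tid in tids:
                if tid not in tgt_store:
                    v.append(Violation("association.dangling_target",
                                       assoc.target, tid,
                                       f"edge target missing for {name!r}"))
                elif assoc.inverse is not None and sid not in \
                        ds.adjacency.get((assoc.target, assoc.inverse), {}) \
                          .get(tid, []):
                    v.append(Violation("association.asymmetric", kind, sid,
                                       f"{name!r} edge to {tid!r} lacks "
                                       f"inverse"))
    return v
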