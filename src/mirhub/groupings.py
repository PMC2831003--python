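"""Derived groupings: seed families and genomic precursor clusters.

Neither grouping is read from release files; both are computed from the
ingested model.

*Seed families* partition mature miRNAs by their seed — bases 2-7 (6mer) or
2-8 (7mer), the primary determinant of target recognition.  Both seed
lengths are materialized side by side, distinguished by the length of the
family sequence, and the family name *is* the seed sequence.

*Precursor clusters* are single-linkage connected components of hairpins
lying close together on the same chromosome (and, by default, the same
strand), the classic signature of a polycistronic miRNA transcript.  The
gap between two placements is measured between interval hulls and floored
at zero for overlapping intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import NoPositionError, SeedTooShortError
from .model import Dataset, PrecursorCluster, SeedFamily, traverse

log = logging.getLogger(__name__)

#: Default maximum hull-to-hull gap (nt) for co-clustering two precursors.
#: Conventional polycistron window; configurable per call.
DEFAULT_MAX_GAP = 10_000


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the genomic clustering."""

    max_gap: int = DEFAULT_MAX_GAP
    same_strand_required: bool = True


def extract_seed(sequence: str, k: int) -> str:
    """Bases 2..k+1 (1-based, inclusive) of a mature sequence, k in {6, 7}."""
    if k not in (6, 7):
        raise ValueError(f"seed length must be 6 or 7, got {k}")
    if len(sequence) < k + 1:
        raise SeedTooShortError(
            f"sequence of length {len(sequence)} cannot carry a {k}mer seed "
            f"(needs >= {k + 1} nt)")
    return sequence[1:1 + k]


def build_seed_families(dataset: Dataset, k: int) -> list:
    """Group every sufficiently long mature by its k-mer seed.

    Matures shorter than k+1 nt are left unassigned and logged.  Rerunning
    replaces the k-length families idempotently; families of the other seed
    length are untouched.  Returns the created families sorted by name.
    """
    for fam in list(dataset.store("seed_family").values()):
        if len(fam.sequence) == k:
            dataset.remove_entity("seed_family", fam.id)

    groups: dict = {}
    for m in dataset.store("mature").values():
        try:
            seed = extract_seed(m.sequence, k)
        except SeedTooShortError:
            log.warning("mature %r too short for a %dmer seed; unassigned",
                        m.name, k)
            continue
        groups.setdefault(seed, []).append(m.name)

    out = []
    for seed in sorted(groups):
        fam = SeedFamily(name=seed)
        dataset.add(fam)
        for mname in groups[seed]:
            dataset.link("seed_family", seed, "matures", mname)
        out.append(fam)
    return out


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, max(s1, s2) - min(e1, e2))


def build_precursor_clusters(dataset: Dataset,
                             params: ClusterParams = ClusterParams()) -> list:
    """Single-linkage clustering of precursors by genomic proximity.

    Two precursors are adjacent iff they have placements on the same
    chromosome (and strand, when required) whose hull gap is at most
    ``params.max_gap``.  Connected components of size >= 2 become clusters
    named ``<species>-cluster-<xsome>-<ordinal>``, ordered by leftmost
    start; singletons and precursors without placements stay unclustered.
    Rerunning replaces all clusters idempotently.
    """
    dataset.unlink_kind("precursor_cluster")

    # union-find over precursor names
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # (xsome[, strand]) -> list of (start, end, precursor)
    by_group: dict = {}
    pos_store = dataset.store("genome_position")
    for (kind, name), adj in dataset.adjacency.items():
        if (kind, name) != ("precursor", "genome_positions"):
            continue
        for pname, pos_ids in adj.items():
            parent.setdefault(pname, pname)
            for pid in pos_ids:
                gp = pos_store[pid]
                key = ((gp.xsome, gp.strand) if params.same_strand_required
                       else (gp.xsome,))
                by_group.setdefault(key, []).append(
                    (gp.contig_start, gp.contig_end, pname))

    # sweep: intervals sorted by start; link to the running component while
    # the gap to its rightmost end stays within max_gap (exact single linkage)
    for intervals in by_group.values():
        intervals.sort()
        run_end, run_first = None, None
        for start, end, pname in intervals:
            if run_end is not None and start - run_end <= params.max_gap:
                union(run_first, pname)
                run_end = max(run_end, end)
            else:
                run_first, run_end = pname, end

    components: dict = {}
    for pname in parent:
        components.setdefault(find(pname), []).append(pname)

    # leftmost placement of each component for naming/ordering
    def leftmost(members):
        best = None
        for pname in members:
            for pid in dataset.neighbors("precursor", pname,
                                         "genome_positions"):
                gp = pos_store[pid]
                key = (gp.xsome, gp.contig_start, gp.contig_end, pname)
                if best is None or key < best:
                    best = key
        return best

    clusters = sorted(
        ((leftmost(members), sorted(members))
         for members in components.values() if len(members) >= 2),
        key=lambda t: t[0])

    out = []
    ordinals: dict = {}
    for (xsome, start, _end, first_pname), members in clusters:
        species = first_pname.split("-")[0]
        n = ordinals.get((species, xsome), 0) + 1
        ordinals[(species, xsome)] = n
        cl = PrecursorCluster(name=f"{species}-cluster-{xsome}-{n}")
        dataset.add(cl)
        for pname in members:
            dataset.link("precursor_cluster", cl.name, "precursors", pname)
        out.append(cl)
    return out


def neighborhood(dataset: Dataset, precursor, window: int) -> list:
    """All other precursors placed within `window` nt of the query.

    A precursor qualifies if any of its placements overlaps
    ``[start - window, end + window]`` of any placement of the query, on the
    same chromosome (strand is ignored: nearby antisense hairpins are still
    neighbours).  Ordered by leftmost start, then name.
    """
    pos_store = dataset.store("genome_position")
    query_pos = [pos_store[pid] for pid in dataset.neighbors(
        "precursor", precursor.id, "genome_positions")]
    if not query_pos:
        raise NoPositionError(
            f"precursor {precursor.id!r} has no genome position")
    hits = {}
    for other in dataset.store("precursor").values():
        if other.id == precursor.id:
            continue
        for pid in dataset.neighbors("precursor", other.id,
                                     "genome_positions"):
            gp = pos_store[pid]
            for q in query_pos:
                if gp.xsome == q.xsome and \
                        gp.contig_start <= q.contig_end + window and \
                        gp.contig_end >= q.contig_start - window:
                    key = (gp.contig_start, other.id)
                    if other.id not in hits or key < hits[other.id]:
                        hits[other.id] = key
    order = sorted(hits.values())
    store = dataset.store("precursor")
    return [store[name] for _, name in order]
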