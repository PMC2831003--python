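"""Seed families, genomic clustering and the neighborhood query."""

import random

import networkx as nx
import pytest

from mirhub.errors import NoPositionError, SeedTooShortError
from mirhub.fixtures import FixtureSpec, generate_release
from mirhub.groupings import (ClusterParams, build_precursor_clusters,
                              build_seed_families, extract_seed,
                              neighborhood)
from mirhub.ingest import build_dataset
from mirhub.model import (Dataset, GenomePosition, Precursor, Species,
                          get_entity)


def positions_dataset(intervals):
    """Dataset with one species and one precursor per (xsome, s, e, strand)."""
    ds = Dataset("test")
    ds.add(Species("syn", "Synthetica test"))
    for i, (xsome, start, end, strand) in enumerate(intervals, start=1):
        name = f"syn-mir-{i}"
        ds.add(Precursor(name=name, accession=f"MI9{i:06d}",
                         sequence="ACGU"))
        ds.link("species", "syn", "precursors", name)
        gp = GenomePosition(f"{name}-pos-1", xsome, start, end, strand)
        ds.add(gp)
        ds.link("precursor", name, "genome_positions", gp.identifier)
    return ds


def memberships(ds):
    return {frozenset(ds.neighbors("precursor_cluster", c.id, "precursors"))
            for c in ds.store("precursor_cluster").values()}


def brute_force_clusters(ds, params):
    """O(n^2) pairwise adjacency + transitive closure via networkx."""
    pos = {}
    for p in ds.store("precursor").values():
        pos[p.id] = [ds.store("genome_position")[i]
                     for i in ds.neighbors("precursor", p.id,
                                           "genome_positions")]
    g = nx.Graph()
    g.add_nodes_from(n for n, ps in pos.items() if ps)
    names = sorted(pos)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for ga in pos[a]:
                for gb in pos[b]:
                    if ga.xsome != gb.xsome:
                        continue
                    if params.same_strand_required and \
                            ga.strand != gb.strand:
                        continue
                    gap = max(0, max(ga.contig_start, gb.contig_start) -
                              min(ga.contig_end, gb.contig_end))
                    if gap <= params.max_gap:
                        g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


class TestExtractSeed:
    def test_six_mer_is_bases_two_to_seven(self):
        assert extract_seed("ACGUACGUACGU", 6) == "CGUACG"

    def test_homopolymer_seven_mer(self):
        assert extract_seed("AAAAAAAA", 7) == "AAAAAAA"

    def test_boundary_too_short(self):
        with pytest.raises(SeedTooShortError):
            extract_seed("ACGUACG", 7)
        assert extract_seed("ACGUACG", 6) == "CGUACG"


class TestSeedFamilies:
    @pytest.mark.parametrize("k", [6, 7])
    def test_matches_brute_force_dictionary_grouping(self, dataset, k):
        build_seed_families(dataset, k)
        oracle = {}
        for m in dataset.store("mature").values():
            if len(m.sequence) >= k + 1:
                oracle.setdefault(m.sequence[1:1 + k], set()).add(m.id)
        got = {f.id: set(dataset.neighbors("seed_family", f.id, "matures"))
               for f in dataset.store("seed_family").values()
               if len(f.sequence) == k}
        assert got == oracle

    def test_partition_law(self, dataset):
        for k in (6, 7):
            build_seed_families(dataset, k)
        for k in (6, 7):
            fams = [f for f in dataset.store("seed_family").values()
                    if len(f.sequence) == k]
            assigned = [m for f in fams
                        for m in dataset.neighbors("seed_family", f.id,
                                                   "matures")]
            eligible = [m.id for m in dataset.store("mature").values()
                        if len(m.sequence) >= k + 1]
            assert sorted(assigned) == sorted(eligible)  # no dup, no gap
            assert len({f.sequence for f in fams}) == len(fams)

    def test_planted_sharing_matches_manifest(self, dataset, manifest):
        for k in (6, 7):
            build_seed_families(dataset, k)
        for k in (6, 7):
            got = {f.id: dataset.neighbors("seed_family", f.id, "matures")
                   for f in dataset.store("seed_family").values()
                   if len(f.sequence) == k}
            assert got == manifest.seed_families[k]
        # the first two 5p matures of each species were planted to share
        fam7 = next(f for f in dataset.store("seed_family").values()
                    if len(f.sequence) == 7 and
                    "zaa-miR-1" in dataset.neighbors("seed_family", f.id,
                                                     "matures"))
        assert "zaa-miR-2" in dataset.neighbors("seed_family", fam7.id,
                                                "matures")

    def test_rerun_is_idempotent_and_per_length(self, dataset):
        build_seed_families(dataset, 6)
        six = {f.id for f in dataset.store("seed_family").values()}
        build_seed_families(dataset, 7)
        build_seed_families(dataset, 6)
        now6 = {f.id for f in dataset.store("seed_family").values()
                if len(f.sequence) == 6}
        now7 = {f.id for f in dataset.store("seed_family").values()
                if len(f.sequence) == 7}
        assert now6 == six and now7  # 7mer families survived the 6mer rerun

    def test_short_mature_left_unassigned(self, tmp_path):
        bundle, _ = generate_release(FixtureSpec(seed=5, short_mature=True),
                                     tmp_path)
        ds = build_dataset(bundle)
        short = [m for m in ds.store("mature").values()
                 if len(m.sequence) == 7]
        assert short
        build_seed_families(ds, 7)
        for m in short:
            assert ds.neighbors("mature", m.id, "seed_families") == []


class TestClusters:
    def test_three_interval_example(self):
        ds = positions_dataset([("chr1", 100, 180, "+"),
                                ("chr1", 900, 980, "+"),
                                ("chr1", 5000, 5080, "+")])
        build_precursor_clusters(ds, ClusterParams(max_gap=1000))
        assert memberships(ds) == {frozenset({"syn-mir-1", "syn-mir-2"})}

    def test_strand_toggle(self):
        intervals = [("chr1", 100, 180, "+"), ("chr1", 900, 980, "-")]
        ds = positions_dataset(intervals)
        build_precursor_clusters(
            ds, ClusterParams(max_gap=1000, same_strand_required=True))
        assert memberships(ds) == set()
        build_precursor_clusters(
            ds, ClusterParams(max_gap=1000, same_strand_required=False))
        assert memberships(ds) == {frozenset({"syn-mir-1", "syn-mir-2"})}

    def test_gap_measured_between_hulls_and_floored(self):
        # book-ended (gap 1), touching-threshold and overlapping intervals
        ds = positions_dataset([("chr1", 100, 200, "+"),
                                ("chr1", 150, 250, "+"),   # overlap: gap 0
                                ("chr1", 261, 300, "+")])  # gap 11 to hull
        build_precursor_clusters(ds, ClusterParams(max_gap=10))
        assert memberships(ds) == {frozenset({"syn-mir-1", "syn-mir-2"})}
        build_precursor_clusters(ds, ClusterParams(max_gap=11))
        assert memberships(ds) == {
            frozenset({"syn-mir-1", "syn-mir-2", "syn-mir-3"})}

    @pytest.mark.parametrize("seed,stranded", [(0, True), (1, True),
                                               (2, False), (3, False)])
    def test_oracle_equivalence_on_random_instances(self, seed, stranded):
        rng = random.Random(seed)
        intervals = []
        for _ in range(200):
            start = rng.randint(1, 200_000)
            intervals.append((rng.choice(["chr1", "chr2", "chr3"]),
                              start, start + rng.randint(60, 120),
                              rng.choice("+-")))
        ds = positions_dataset(intervals)
        params = ClusterParams(max_gap=2000, same_strand_required=stranded)
        build_precursor_clusters(ds, params)
        assert memberships(ds) == brute_force_clusters(ds, params)

    def test_multi_position_precursor_bridges_chromosomes(self):
        ds = positions_dataset([("chr1", 100, 180, "+"),
                                ("chr2", 100, 180, "+")])
        # a third precursor placed on both chromosomes links 1 and 2
        ds.add(Precursor(name="syn-mir-3", accession="MI9000003",
                         sequence="ACGU"))
        ds.link("species", "syn", "precursors", "syn-mir-3")
        for j, xsome in enumerate(("chr1", "chr2"), start=1):
            gp = GenomePosition(f"syn-mir-3-pos-{j}", xsome, 300, 380, "+")
            ds.add(gp)
            ds.link("precursor", "syn-mir-3", "genome_positions",
                    gp.identifier)
        params = ClusterParams(max_gap=1000)
        build_precursor_clusters(ds, params)
        assert memberships(ds) == {
            frozenset({"syn-mir-1", "syn-mir-2", "syn-mir-3"})}
        assert memberships(ds) == brute_force_clusters(ds, params)

    def test_monotone_coarsening_in_max_gap(self):
        rng = random.Random(11)
        intervals = []
        for _ in range(120):
            start = rng.randint(1, 60_000)
            intervals.append(("chr1", start, start + rng.randint(60, 120),
                              rng.choice("+-")))
        ds = positions_dataset(intervals)
        previous = None
        for gap in (0, 100, 500, 2000, 10_000, 100_000):
            build_precursor_clusters(ds, ClusterParams(max_gap=gap))
            part = memberships(ds)
            if previous is not None:
                for comp in previous:
                    assert any(comp <= larger for larger in part), \
                        f"cluster {comp} split when max_gap rose to {gap}"
            previous = part

    def test_planted_boundary_gaps_split_exactly(self, dataset, manifest):
        build_precursor_clusters(dataset, manifest.cluster_params)
        got = {c.id: dataset.neighbors("precursor_cluster", c.id,
                                       "precursors")
               for c in dataset.store("precursor_cluster").values()}
        assert got == manifest.expected_clusters
        # gap == max_gap keeps zaa-mir-3 in; gap == max_gap+1 keeps -4 out
        members = got["zaa-cluster-chr1-1"]
        assert "zaa-mir-3" in members and "zaa-mir-4" not in members
        build_precursor_clusters(
            dataset, ClusterParams(max_gap=manifest.cluster_params.max_gap,
                                   same_strand_required=False))
        got2 = {c.id: dataset.neighbors("precursor_cluster", c.id,
                                        "precursors")
                for c in dataset.store("precursor_cluster").values()}
        assert got2 == manifest.expected_clusters_unstranded

    def test_determinism(self, dataset, manifest):
        build_precursor_clusters(dataset, manifest.cluster_params)
        first = {c.id: dataset.neighbors("precursor_cluster", c.id,
                                         "precursors")
                 for c in dataset.store("precursor_cluster").values()}
        build_precursor_clusters(dataset, manifest.cluster_params)
        second = {c.id: dataset.neighbors("precursor_cluster", c.id,
                                          "precursors")
                  for c in dataset.store("precursor_cluster").values()}
        assert first == second


class TestNeighborhood:
    def fixture_ds(self):
        return positions_dataset([("chr1", 100, 180, "+"),
                                  ("chr1", 900, 980, "+"),
                                  ("chr1", 5000, 5080, "+")])

    def test_window_1000_finds_middle_only(self):
        ds = self.fixture_ds()
        query = get_entity(ds, "precursor", "syn-mir-1")
        assert [p.id for p in neighborhood(ds, query, 1000)] == ["syn-mir-2"]

    def test_window_zero_requires_contact(self):
        ds = self.fixture_ds()
        query = get_entity(ds, "precursor", "syn-mir-1")
        assert neighborhood(ds, query, 0) == []

    def test_saturating_window_returns_all_same_chromosome(self):
        ds = self.fixture_ds()
        query = get_entity(ds, "precursor", "syn-mir-2")
        assert [p.id for p in neighborhood(ds, query, 10 ** 9)] == \
            ["syn-mir-1", "syn-mir-3"]

    def test_no_position_signal(self):
        ds = self.fixture_ds()
        ds.add(Precursor(name="syn-mir-9", accession="MI9000009",
                         sequence="ACGU"))
        with pytest.raises(NoPositionError):
            neighborhood(ds, get_entity(ds, "precursor", "syn-mir-9"), 1000)
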