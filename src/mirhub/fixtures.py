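"""Deterministic synthetic release generator with a ground-truth manifest.

Generates a complete miRBase-style release — EMBL-dialect hairpin records,
family file, per-species GFF coordinates, species/context tab dumps and the
FASTA pair — entirely from a seeded RNG, so every other module is testable
without downloading anything.  The accompanying :class:`Manifest` records
exactly what ingest and derivation must reproduce.

Planted structures (all edge cases the model contract mentions):

* a mature shared verbatim by two hairpins (the many-to-many link),
* star matures with a ``*`` suffix,
* a precursor with two genome positions,
* one species without a genome assembly (no coordinate file),
* consecutive loci whose gaps bracket the clustering threshold exactly
  (``max_gap`` and ``max_gap + 1``) plus an antisense neighbour,
* groups of matures forced to share their 7mer (hence 6mer) seed,
* a shared literature reference across hairpins,
* optionally a 7 nt mature (long enough for a 6mer seed, too short for 7).

Accession namespaces are synthetic (MI9…, MIMAT9…, MIPF9…) so fixtures can
never be mistaken for real release data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .groupings import DEFAULT_MAX_GAP, ClusterParams
from .ingest import ReleaseBundle
from .model import Dataset

RNA = "ACGU"

_SPECIES_NAMES = ["Synthetica alpha", "Synthetica beta", "Synthetica gamma",
                  "Synthetica delta", "Synthetica epsilon"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic release."""

    seed: int = 42
    n_species: int = 3
    precursors_per_species: int = 5
    star_fraction: float = 0.5        # even-indexed precursors get a star mature
    shared_mature: bool = True        # precursors 3 and 4 share their 5p mature
    family_sizes: tuple = (3, 2)      # curated families spanning species
    seed_share_group: int = 2         # first N 5p matures per species share a 7mer seed
    contexts_per_precursor: int = 1
    shared_paper: bool = True         # precursors 1 and 2 per species cite one paper
    cluster_max_gap: int = DEFAULT_MAX_GAP
    species_without_assembly: int = 1  # trailing species lack coordinate files
    short_mature: bool = False        # plant one 7 nt mature (edge case)

    def __post_init__(self):
        if self.n_species < 1 or self.precursors_per_species < 1:
            raise ValueError("need at least one species and one precursor")


@dataclass
class Manifest:
    """Ground truth a built dataset (and derivation) must reproduce exactly."""

    version: str
    counts: dict
    species: dict                 # code -> attr dict
    precursors: dict              # name -> attrs + association lists
    matures: dict                 # name -> attrs + precursor list
    families: dict                # name -> {"accession", "members"}
    seed_families: dict           # k -> {seed: sorted mature names}
    cluster_params: "ClusterParams"
    expected_clusters: dict       # name -> sorted precursor names (stranded)
    expected_clusters_unstranded: dict

    # -- comparison helpers -------------------------------------------------

    def mismatches(self, ds: Dataset) -> list:
        """Differences between an ingested dataset and the manifest."""
        diffs = []
        if ds.release_version != self.version:
            diffs.append(f"release_version {ds.release_version!r} != "
                         f"{self.version!r}")
        for kind, expected in self.counts.items():
            got = len(ds.store(kind))
            if got != expected:
                diffs.append(f"count[{kind}] {got} != {expected}")
        for code, attrs in self.species.items():
            sp = ds.store("species").get(code)
            if sp is None:
                diffs.append(f"species {code} missing")
                continue
            for k, v in attrs.items():
                if getattr(sp, k) != v:
                    diffs.append(f"species {code}.{k} mismatch")
        for name, exp in self.precursors.items():
            p = ds.store("precursor").get(name)
            if p is None:
                diffs.append(f"precursor {name} missing")
                continue
            for k in ("accession", "sequence", "description", "comment"):
                if getattr(p, k) != exp[k]:
                    diffs.append(f"precursor {name}.{k} mismatch")
            if ds.neighbors("precursor", name, "matures") != exp["matures"]:
                diffs.append(f"precursor {name} matures mismatch")
            if ds.neighbors("precursor", name, "papers") != exp["papers"]:
                diffs.append(f"precursor {name} papers mismatch")
            if ds.neighbors("species", exp["species"], "precursors").count(
                    name) != 1:
                diffs.append(f"precursor {name} species link mismatch")
            got_pos = sorted(
                (gp.xsome, gp.contig_start, gp.contig_end, gp.strand)
                for gp in (ds.store("genome_position")[pid]
                           for pid in ds.neighbors("precursor", name,
                                                   "genome_positions")))
            if got_pos != sorted(exp["positions"]):
                diffs.append(f"precursor {name} positions mismatch")
            n_ctx = len(ds.neighbors("precursor", name, "genome_contexts"))
            if n_ctx != exp["n_contexts"]:
                diffs.append(f"precursor {name} context count mismatch")
        for name, exp in self.matures.items():
            m = ds.store("mature").get(name)
            if m is None:
                diffs.append(f"mature {name} missing")
                continue
            if m.accession != exp["accession"] or \
                    m.sequence != exp["sequence"]:
                diffs.append(f"mature {name} attrs mismatch")
            if ds.neighbors("mature", name, "precursors") != \
                    exp["precursors"]:
                diffs.append(f"mature {name} precursors mismatch")
        for fname, exp in self.families.items():
            fam = ds.store("precursor_family").get(fname)
            if fam is None or fam.accession != exp["accession"]:
                diffs.append(f"family {fname} missing or wrong accession")
                continue
            if ds.neighbors("precursor_family", fname, "precursors") != \
                    exp["members"]:
                diffs.append(f"family {fname} members mismatch")
        return diffs

    def grouping_mismatches(self, ds: Dataset) -> list:
        """Differences between derived groupings and the planted plan.

        Call after build_seed_families(ds, 6), build_seed_families(ds, 7)
        and build_precursor_clusters(ds, self.cluster_params).
        """
        diffs = []
        for k, expected in self.seed_families.items():
            got = {
                fam.id: ds.neighbors("seed_family", fam.id, "matures")
                for fam in ds.store("seed_family").values()
                if len(fam.sequence) == k
            }
            if got != expected:
                diffs.append(f"{k}mer seed families mismatch: "
                             f"{got} != {expected}")
        got_clusters = {
            cl.id: ds.neighbors("precursor_cluster", cl.id, "precursors")
            for cl in ds.store("precursor_cluster").values()
        }
        if got_clusters != self.expected_clusters:
            diffs.append(f"clusters mismatch: {got_clusters} != "
                         f"{self.expected_clusters}")
        return diffs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _species_code(i: int) -> str:
    return "z" + chr(ord("a") + i // 26) + chr(ord("a") + i % 26)


def _rand_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(RNA) for _ in range(n))


def generate_release(spec: FixtureSpec, destination) -> tuple:
    """Write a complete synthetic release; return (ReleaseBundle, Manifest).

    Byte-identical output for identical specs: every random draw comes from
    one seeded RNG and all iteration is insertion-ordered.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    version = f"synthetic-{spec.seed}"

    mi_counter = [9000000]
    mimat_counter = [9000000]

    def next_mi():
        mi_counter[0] += 1
        return f"MI{mi_counter[0]}"

    def next_mimat():
        mimat_counter[0] += 1
        return f"MIMAT{mimat_counter[0]}"

    species = []
    for si in range(spec.n_species):
        code = _species_code(si)
        has_assembly = si < spec.n_species - spec.species_without_assembly
        species.append({
            "abbreviation": code,
            "name": _SPECIES_NAMES[si % len(_SPECIES_NAMES)] +
                    ("" if si < len(_SPECIES_NAMES) else f" {si}"),
            "division": "SYN",
            "taxonomy": f"Synthetica; clade{si};",
            "genome_assembly": f"SYN{si + 1}.0" if has_assembly else "",
        })

    # ---- matures then hairpins -------------------------------------------
    precursors = []   # list of dicts
    matures = {}      # name -> dict(accession, sequence, precursors=[...])

    for sp in species:
        code = sp["abbreviation"]
        shared_seq = None
        seed7 = None
        for pi in range(spec.precursors_per_species):
            pname = f"{code}-mir-{pi + 1}"
            # 5p mature: planted seed sharing for the first group, a shared
            # mature object for precursors 3 and 4
            share_with_prev = (spec.shared_mature and pi == 3 and
                               spec.precursors_per_species >= 4)
            if share_with_prev:
                mname = f"{code}-miR-3"
                m5 = matures[mname]
            else:
                mname = f"{code}-miR-{pi + 1}"
                mlen = 7 if (spec.short_mature and pi ==
                             spec.precursors_per_species - 1 and
                             code == species[0]["abbreviation"]) else 22
                mseq = _rand_rna(rng, mlen)
                if pi < spec.seed_share_group and mlen >= 8:
                    if seed7 is None:
                        seed7 = mseq[1:8]
                    else:
                        mseq = mseq[0] + seed7 + mseq[8:]
                m5 = {"accession": next_mimat(), "sequence": mseq,
                      "evidence": "experimental",
                      "experiment": "cloned", "similarity": "",
                      "precursors": []}
                matures[mname] = m5
            if pi == 3 and share_with_prev:
                pass  # shared object, no new sequence drawn
            m5["precursors"].append(pname)

            has_star = (spec.star_fraction > 0 and pi % 2 == 0 and
                        not share_with_prev)
            star = None
            if has_star:
                star_name = f"{code}-miR-{pi + 1}*"
                star = {"accession": next_mimat(),
                        "sequence": _rand_rna(rng, 22),
                        "evidence": "experimental",
                        "experiment": "cloned", "similarity": "",
                        "precursors": [pname]}
                matures[star_name] = star

            f5 = _rand_rna(rng, rng.randint(8, 12))
            if star is not None:
                mid = _rand_rna(rng, rng.randint(10, 16))
                f3 = _rand_rna(rng, rng.randint(6, 10))
                hairpin = (f5 + m5["sequence"] + mid + star["sequence"] + f3)
                feats = [
                    (m5["accession"], mname, len(f5) + 1,
                     len(f5) + len(m5["sequence"])),
                    (star["accession"], star_name,
                     len(f5) + len(m5["sequence"]) + len(mid) + 1,
                     len(f5) + len(m5["sequence"]) + len(mid) +
                     len(star["sequence"])),
                ]
            else:
                f3 = _rand_rna(rng, rng.randint(25, 35))
                hairpin = f5 + m5["sequence"] + f3
                feats = [(m5["accession"], mname, len(f5) + 1,
                          len(f5) + len(m5["sequence"]))]

            precursors.append({
                "name": pname,
                "accession": next_mi(),
                "species": code,
                "description": f"{sp['name']} {pname} stem-loop",
                "comment": f"synthetic hairpin number {pi + 1} for species "
                           f"{code}",
                "sequence": hairpin,
                "features": feats,
                "papers": [],
                "positions": [],
                "n_contexts": spec.contexts_per_precursor,
            })
            _ = shared_seq  # clarity only

    by_name = {p["name"]: p for p in precursors}

    # ---- papers ----------------------------------------------------------
    papers = {}
    medline_counter = 90000000
    for sp in species:
        code = sp["abbreviation"]
        sp_precs = [p for p in precursors if p["species"] == code]
        shared_medline = None
        if spec.shared_paper and len(sp_precs) >= 2:
            medline_counter += 1
            shared_medline = str(medline_counter)
            papers[shared_medline] = {
                "title": f"Survey of {code} synthetic microRNAs",
                "authors": "Doe J., Roe R.",
                "journal": f"J Synth Biol. {len(papers) + 1}:1-10(2009).",
            }
        for i, p in enumerate(sp_precs):
            medline_counter += 1
            medline = str(medline_counter)
            papers[medline] = {
                "title": f"Cloning of {p['name']}",
                "authors": "Doe J.",
                "journal": f"J Synth Biol. {len(papers) + 1}:11-20(2009).",
            }
            p["papers"].append(medline)
            if shared_medline is not None and i < 2:
                p["papers"].append(shared_medline)

    # ---- curated families ------------------------------------------------
    # disjoint curated families (a precursor belongs to at most one),
    # spanning species: members are taken species-round-robin
    families = {}
    candidates = [f"{sp['abbreviation']}-mir-{pi + 1}"
                  for pi in range(spec.precursors_per_species)
                  for sp in species]
    taken = 0
    for fi, size in enumerate(spec.family_sizes):
        members = sorted(candidates[taken:taken + size])
        taken += size
        if not members:
            continue
        families[f"synfam-{fi + 1}"] = {
            "accession": f"MIPF{9000000 + fi + 1}", "members": members}

    # ---- genome positions (cluster plan) ---------------------------------
    gap_plan = {}  # species code -> list of (name, xsome, start, end, strand, gap_to_prev)
    for si, sp in enumerate(species):
        if not sp["genome_assembly"]:
            continue
        code = sp["abbreviation"]
        sp_precs = [p for p in precursors if p["species"] == code]
        xsome = f"chr{si + 1}"
        plan = []
        cursor = 1000
        for i, p in enumerate(sp_precs):
            length = len(p["sequence"])
            if i == 0:
                gap = None
                start = cursor
            else:
                if si == 0:
                    if i == 1:
                        gap = 720
                    elif i == 2:
                        gap = spec.cluster_max_gap
                    elif i == len(sp_precs) - 1:
                        gap = 100
                    else:
                        gap = spec.cluster_max_gap + 1
                else:
                    gap = 5 * spec.cluster_max_gap
                start = cursor + gap
            end = start + length - 1
            strand = "-" if (si == 0 and i == len(sp_precs) - 1 and
                             len(sp_precs) >= 2) else "+"
            p["positions"].append((xsome, start, end, strand))
            plan.append((p["name"], xsome, start, end, strand, gap))
            cursor = end
        gap_plan[code] = plan
        # planted multi-position precursor: second assembly species
        if si == 1:
            extra_p = sp_precs[0]
            length = len(extra_p["sequence"])
            extra_p["positions"].append(("chrM", 5000, 5000 + length - 1,
                                         "+"))

    # expected clusters from the *plan* (walk planted gaps, never the
    # clustering implementation)
    def plan_clusters(stranded: bool) -> dict:
        runs = []
        for code, plan in sorted(gap_plan.items()):
            comp = []
            prev_strand = None
            for (name, xsome, start, end, strand, gap) in plan:
                linked = (gap is not None and gap <= spec.cluster_max_gap and
                          (not stranded or strand == prev_strand))
                if linked:
                    comp.append((name, start))
                else:
                    if len(comp) >= 2:
                        runs.append((xsome, comp))
                    comp = [(name, start)]
                prev_strand = strand
            if len(comp) >= 2:
                runs.append((comp_xsome := plan[0][1], comp))
        clusters = {}
        ordinals = {}
        for xsome, comp in sorted(runs, key=lambda t: (t[0],
                                                       min(s for _, s in
                                                           comp))):
            first = min(comp, key=lambda t: t[1])[0]
            code = first.split("-")[0]
            n = ordinals.get((code, xsome), 0) + 1
            ordinals[(code, xsome)] = n
            clusters[f"{code}-cluster-{xsome}-{n}"] = sorted(
                name for name, _ in comp)
        return clusters

    params = ClusterParams(max_gap=spec.cluster_max_gap,
                           same_strand_required=True)
    expected_clusters = plan_clusters(stranded=True)
    expected_unstranded = plan_clusters(stranded=False)

    # ---- planted seed families (brute-force dictionary over the plan) ----
    seed_families = {}
    for k in (6, 7):
        groups = {}
        for mname, m in matures.items():
            if len(m["sequence"]) >= k + 1:
                groups.setdefault(m["sequence"][1:1 + k], []).append(mname)
        seed_families[k] = {s: sorted(ms) for s, ms in sorted(groups.items())}

    # ---- write files -----------------------------------------------------
    _write_hairpin_records(dest / "miRNA.dat", precursors, papers, matures)
    _write_family_file(dest / "miFam.dat", families, by_name)
    gdir = dest / "genomes"
    for code, plan in sorted(gap_plan.items()):
        gdir.mkdir(exist_ok=True)
        lines = []
        for (name, xsome, start, end, strand, _gap) in plan:
            acc = by_name[name]["accession"]
            lines.append(f'{xsome}\t.\tmiRNA\t{start}\t{end}\t.\t{strand}'
                         f'\t.\tACC="{acc}"; ID="{name}";')
        for p in precursors:
            if p["species"] == code:
                for (xsome, start, end, strand) in p["positions"][1:]:
                    lines.append(f'{xsome}\t.\tmiRNA\t{start}\t{end}\t.'
                                 f'\t{strand}\t.\tACC="{p["accession"]}"; '
                                 f'ID="{p["name"]}";')
        (gdir / f"{code}.gff").write_text(
            "# synthetic coordinate file\n" + "\n".join(lines) + "\n")

    ctx_lines = []
    ctx_types = ["intron", "exon", "intergenic"]
    ctx_senses = ["sense", "antisense", "unknown"]
    gene_no = 0
    for p in precursors:
        for ci in range(spec.contexts_per_precursor):
            gene_no += 1
            ctx_lines.append("\t".join([
                p["accession"], "ensembl", f"SYNGENE{gene_no}",
                ctx_senses[gene_no % 3], ctx_types[gene_no % 3]]))
    (dest / "context.tsv").write_text(
        "# precursor\tsource\ttranscript\tsense\ttype\n" +
        "\n".join(ctx_lines) + "\n")

    (dest / "species.tsv").write_text(
        "# abbreviation\tname\tdivision\ttaxonomy\tassembly\n" +
        "\n".join("\t".join([sp["abbreviation"], sp["name"], sp["division"],
                             sp["taxonomy"], sp["genome_assembly"]])
                  for sp in species) + "\n")

    _write_fasta(dest / "hairpin.fa",
                 [(p["name"], p["accession"], p["sequence"])
                  for p in precursors])
    _write_fasta(dest / "mature.fa",
                 [(name, m["accession"], m["sequence"])
                  for name, m in matures.items()])
    (dest / "VERSION").write_text(version + "\n")

    # ---- manifest --------------------------------------------------------
    n_positions = sum(len(p["positions"]) for p in precursors)
    manifest = Manifest(
        version=version,
        counts={
            "species": len(species),
            "precursor": len(precursors),
            "mature": len(matures),
            "precursor_family": len(families),
            "paper": len(papers),
            "genome_position": n_positions,
            "genome_context": len(precursors) * spec.contexts_per_precursor,
            "seed_family": 0,
            "precursor_cluster": 0,
        },
        species={sp["abbreviation"]: dict(sp) for sp in species},
        precursors={
            p["name"]: {
                "accession": p["accession"],
                "sequence": p["sequence"],
                "description": p["description"],
                "comment": p["comment"],
                "species": p["species"],
                "matures": sorted(n for n, _a, _s, _e in
                                  ((f[1], f[0], f[2], f[3])
                                   for f in p["features"])),
                "papers": sorted(p["papers"]),
                "positions": list(p["positions"]),
                "n_contexts": p["n_contexts"],
            } for p in precursors
        },
        matures={
            name: {"accession": m["accession"], "sequence": m["sequence"],
                   "precursors": sorted(m["precursors"])}
            for name, m in matures.items()
        },
        families=families,
        seed_families=seed_families,
        cluster_params=params,
        expected_clusters=expected_clusters,
        expected_clusters_unstranded=expected_unstranded,
    )
    bundle = ReleaseBundle.from_dir(dest, version=version)
    return bundle, manifest


# ---------------------------------------------------------------------------
# File writers (the exact dialects mirbase_ingest consumes)
# ---------------------------------------------------------------------------

def _wrap_sequence(seq: str) -> list:
    lines = []
    low = seq.lower()
    for i in range(0, len(low), 60):
        chunk = low[i:i + 60]
        groups = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        count = min(i + 60, len(low))
        lines.append(f"     {groups:<66}{count:>9}")
    return lines


def _write_hairpin_records(path: Path, precursors, papers, matures):
    out = []
    for p in precursors:
        seq = p["sequence"]
        counts = {b: seq.count(b) for b in "ACGU"}
        out.append(f"ID   {p['name']}    standard; RNA; "
                   f"{p['species'].upper()}; {len(seq)} BP.")
        out.append("XX")
        out.append(f"AC   {p['accession']};")
        out.append("XX")
        out.append(f"DE   {p['description']}")
        out.append("XX")
        for ri, medline in enumerate(p["papers"], start=1):
            ref = papers[medline]
            out.append(f"RN   [{ri}]")
            out.append(f"RX   MEDLINE; {medline}.")
            out.append(f"RA   {ref['authors']};")
            out.append(f"RT   \"{ref['title']}\";")
            out.append(f"RL   {ref['journal']}")
            out.append("XX")
        for cc_line in p["comment"].split("\n"):
            out.append(f"CC   {cc_line}")
        out.append("XX")
        out.append("FH   Key             Location/Qualifiers")
        out.append("FH")
        for acc, product, start, end in p["features"]:
            out.append(f"FT   miRNA           {start}..{end}")
            out.append(f"FT                   /accession=\"{acc}\"")
            out.append(f"FT                   /product=\"{product}\"")
            m = matures[product]
            out.append(f"FT                   /evidence={m['evidence']}")
            out.append(f"FT                   /experiment="
                       f"\"{m['experiment']}\"")
        out.append("XX")
        other = len(seq) - sum(counts.values())
        out.append(f"SQ   Sequence {len(seq)} BP; {counts['A']} A; "
                   f"{counts['C']} C; {counts['G']} G; {counts['U']} U; "
                   f"{other} other;")
        out.extend(_wrap_sequence(seq))
        out.append("//")
    path.write_text("\n".join(out) + "\n")


def _write_family_file(path: Path, families, by_name):
    out = []
    for fname, fam in families.items():
        out.append(f"AC   {fam['accession']}")
        out.append(f"ID   {fname}")
        for member in fam["members"]:
            out.append(f"MI   {by_name[member]['accession']}  {member}")
        out.append("//")
    path.write_text("\n".join(out) + "\n")


def _write_fasta(path: Path, records):
    out = []
    for name, acc, seq in records:
        out.append(f">{name} {acc}")
        out.append(seq)
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 42) -> FixtureSpec:
    """Canned fixture parameterizations: 'small' or 'edgecases'."""
    if name == "small":
        return FixtureSpec(seed=seed)
    if name == "edgecases":
        return FixtureSpec(seed=seed, short_mature=True)
    raise ValueError(f"unknown preset {name!r} (use 'small' or 'edgecases')")
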