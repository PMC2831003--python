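"""Parse a miRBase-style release into a validated :class:`~mirhub.model.Dataset`.

A release bundle is a directory of flat files in the dialects miRBase has
published for years: an EMBL-style hairpin record file (the only mandatory
member), a precursor-family membership file, per-species GFF coordinate
files, hairpin/mature FASTA, and two tab-delimited dumps (species table,
genome-context table) whose layout is fixed by this package.

The defect policy is skip-and-log: malformed records or lines are reported
through the module logger and dropped; only a missing hairpin record file is
fatal.  Real releases contain oddities and ingest must be total.
"""

from __future__ import annotations

import gzip
import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import FetchError, MirhubError, UnknownVersionError
from .model import (Dataset, GenomeContext, GenomePosition, Mature, Paper,
                    Precursor, PrecursorFamily, Species)

log = logging.getLogger(__name__)

_STRANDS = {"+": "+", "-": "-", "1": "+", "-1": "-"}


# ---------------------------------------------------------------------------
# Raw record types
# ---------------------------------------------------------------------------

@dataclass
class MatureFeature:
    """An FT miRNA feature inside a hairpin record (1-based inclusive)."""

    accession: str
    product: str
    start: int
    end: int
    evidence: str = ""
    experiment: str = ""
    similarity: str = ""


@dataclass
class Reference:
    medline: str
    title: str = ""
    authors: str = ""
    journal: str = ""


@dataclass
class RawPrecursorRecord:
    """One parsed EMBL-dialect hairpin record, before model linking."""

    name: str
    accession: str
    description: str = ""
    comment: str = ""
    species_code: str = ""
    sequence: str = ""
    matures: list = field(default_factory=list)
    references: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# EMBL-dialect hairpin records
# ---------------------------------------------------------------------------

def _normalize_rna(raw: str) -> str:
    return raw.upper().replace("T", "U")


def parse_hairpin_records(text: str) -> list:
    """Parse a concatenation of EMBL-dialect records terminated by ``//``.

    Returns one :class:`RawPrecursorRecord` per well-formed record.  A record
    that cannot be parsed, or whose mature feature coordinates fall outside
    the hairpin sequence, is logged with its starting line number and
    skipped.
    """
    records = []
    block: list = []
    block_start = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("//"):
            if block:
                rec = _parse_record_block(block, block_start)
                if rec is not None:
                    records.append(rec)
            block, block_start = [], lineno + 1
        else:
            if not block:
                block_start = lineno
            block.append(line)
    if any(l.strip() for l in block):
        rec = _parse_record_block(block, block_start)
        if rec is not None:
            records.append(rec)
    return records


def _parse_record_block(lines: list, start_line: int):
    try:
        rec = _parse_record_lines(lines)
    except Exception as exc:  # noqa: BLE001 - totality: skip + log, never raise
        log.warning("skipping malformed record at line %d: %s",
                    start_line, exc)
        return None
    for feat in rec.matures:
        if not (1 <= feat.start <= feat.end <= len(rec.sequence)):
            log.warning("skipping record %r (line %d): feature %s "
                        "coordinates %d..%d outside 1..%d", rec.name,
                        start_line, feat.accession, feat.start, feat.end,
                        len(rec.sequence))
            return None
    return rec


def _parse_record_lines(lines: list) -> RawPrecursorRecord:
    name = accession = ""
    desc_parts: list = []
    comment_parts: list = []
    seq_parts: list = []
    references: list = []
    matures: list = []
    cur_ref: Optional[dict] = None
    cur_feat: Optional[MatureFeature] = None
    in_seq = False

    def flush_ref():
        nonlocal cur_ref
        if cur_ref is not None and cur_ref.get("medline"):
            references.append(Reference(
                medline=cur_ref["medline"],
                title=" ".join(cur_ref.get("title", [])),
                authors=", ".join(cur_ref.get("authors", [])),
                journal=" ".join(cur_ref.get("journal", []))))
        cur_ref = None

    for line in lines:
        code, _, rest = line[:2], line[2:5], line[5:].rstrip()
        if in_seq:
            seq_parts.append(re.sub(r"[\d\s/]", "", line))
            continue
        if code == "ID":
            name = rest.split()[0]
        elif code == "AC":
            accession = rest.split(";")[0].strip()
        elif code == "DE":
            desc_parts.append(rest.strip())
        elif code == "CC":
            comment_parts.append(rest.strip())
        elif code == "RN":
            flush_ref()
            cur_ref = {"title": [], "authors": [], "journal": []}
        elif code == "RX" and cur_ref is not None:
            m = re.match(r"\s*(MEDLINE|PUBMED);\s*(\d+)", rest)
            if m and not cur_ref.get("medline"):
                cur_ref["medline"] = m.group(2)
        elif code == "RT" and cur_ref is not None:
            cur_ref["title"].append(rest.strip().strip(';').strip('"'))
        elif code == "RA" and cur_ref is not None:
            cur_ref["authors"].append(rest.strip().rstrip(";").rstrip(","))
        elif code == "RL" and cur_ref is not None:
            cur_ref["journal"].append(rest.strip())
        elif code == "FT":
            body = line[5:].rstrip()
            stripped = body.strip()
            if not stripped.startswith("/"):
                key, _, loc = stripped.partition(" ")
                if key == "miRNA":
                    m = re.match(r"(\d+)\.\.(\d+)", loc.strip())
                    if not m:
                        raise ValueError(f"bad miRNA location {loc!r}")
                    cur_feat = MatureFeature("", "", int(m.group(1)),
                                             int(m.group(2)))
                    matures.append(cur_feat)
                else:
                    cur_feat = None  # foreign feature kind: ignored
            elif cur_feat is not None:
                m = re.match(r'/(\w+)=\"?([^\"]*)\"?$', stripped)
                if m:
                    key, value = m.groups()
                    if key == "accession":
                        cur_feat.accession = value
                    elif key == "product":
                        cur_feat.product = value
                    elif key in ("evidence", "experiment", "similarity"):
                        setattr(cur_feat, key, value)
        elif code == "SQ":
            in_seq = True

    if not name:
        raise ValueError("record has no ID line")
    if not accession:
        raise ValueError(f"record {name!r} has no AC line")
    flush_ref()
    sequence = _normalize_rna("".join(seq_parts))
    if not sequence:
        raise ValueError(f"record {name!r} has no sequence")
    return RawPrecursorRecord(
        name=name, accession=accession,
        description=" ".join(desc_parts),
        comment=" ".join(comment_parts),
        species_code=name.split("-")[0],
        sequence=sequence, matures=matures, references=references)


# ---------------------------------------------------------------------------
# Family file (miFam.dat dialect)
# ---------------------------------------------------------------------------

def parse_family_file(text: str) -> list:
    """Parse AC/ID/MI family blocks into (accession, name, [member MIs])."""
    families = []
    acc = name = ""
    members: list = []
    start_line = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("//"):
            if acc or name or members:
                if name and members:
                    families.append((acc, name, members))
                else:
                    log.warning("skipping malformed family block at line %d",
                                start_line)
            acc, name, members, start_line = "", "", [], lineno + 1
        elif line.startswith("AC"):
            acc = line[2:].strip().rstrip(";")
        elif line.startswith("ID"):
            name = line[2:].strip()
        elif line.startswith("MI"):
            toks = line[2:].split()
            if toks:
                members.append(toks[0])
    if name and members:
        families.append((acc, name, members))
    return families


# ---------------------------------------------------------------------------
# Coordinate GFF
# ---------------------------------------------------------------------------

_ACC_IN_ATTRS = re.compile(r"\b(MI\d+)\b")
_KEYVAL = re.compile(r'(\w+)\s*=?\s*"?([^";]+)"?')


def parse_coordinates(text: str, species: str = "") -> list:
    """Parse GFF-style coordinate lines into placement tuples.

    Accepts both the quoted GFF2-ish dialect (``ACC="MI0000060";
    ID="cel-let-7";``) and GFF3 attributes (``ID=MI0000060;Name=cel-let-7``).
    Returns ``(precursor_identifier, xsome, start, end, strand)`` tuples with
    1-based inclusive coordinates preserved verbatim.  Malformed lines are
    skipped and logged.
    """
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            log.warning("coordinates line %d: expected 9 columns, got %d",
                        lineno, len(cols))
            continue
        xsome, _, _, start_s, end_s, _, strand, _, attrs = cols[:9]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            log.warning("coordinates line %d: non-integer coordinates",
                        lineno)
            continue
        if start > end:
            log.warning("coordinates line %d: start %d > end %d",
                        lineno, start, end)
            continue
        if strand not in _STRANDS:
            log.warning("coordinates line %d: bad strand %r", lineno, strand)
            continue
        ident = None
        m = _ACC_IN_ATTRS.search(attrs)
        if m:
            ident = m.group(1)
        else:
            kv = dict(_KEYVAL.findall(attrs))
            ident = kv.get("ID") or kv.get("Name") or kv.get("ACC")
        if not ident:
            log.warning("coordinates line %d: no precursor identifier in "
                        "attributes %r", lineno, attrs)
            continue
        out.append((ident.strip(), xsome, start, end, _STRANDS[strand]))
    return out


# ---------------------------------------------------------------------------
# Tab-delimited dumps (dialect fixed by this package)
# ---------------------------------------------------------------------------

def parse_context_table(text: str) -> list:
    """Rows: precursor id, transcript_source, transcript_name, overlap_sense,
    overlap_type.  Duplicate rows stay duplicated (two real overlaps)."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 5:
            log.warning("context line %d: expected 5 columns, got %d",
                        lineno, len(cols))
            continue
        out.append(tuple(c.strip() for c in cols))
    return out


def parse_species_table(text: str) -> list:
    """Rows: abbreviation, name, division, taxonomy, genome_assembly."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 5:
            log.warning("species line %d: expected 5 columns, got %d",
                        lineno, len(cols))
            continue
        out.append(tuple(c.strip() for c in cols))
    return out


def parse_fasta_sequences(text: str) -> dict:
    """Accession -> RNA sequence from a release FASTA (headers ``>name acc``)."""
    seqs: dict = {}
    acc = None
    for line in text.splitlines():
        if line.startswith(">"):
            toks = line[1:].split()
            acc = toks[1] if len(toks) > 1 else (toks[0] if toks else None)
            if acc is not None:
                seqs[acc] = ""
        elif acc is not None:
            seqs[acc] += _normalize_rna(line.strip())
    return seqs


# ---------------------------------------------------------------------------
# Release bundle
# ---------------------------------------------------------------------------

@dataclass
class ReleaseBundle:
    """File handles for one release; only the hairpin records are mandatory."""

    version: str
    hairpin_records: Optional[Path] = None
    family_file: Optional[Path] = None
    coordinates: dict = field(default_factory=dict)  # species code -> Path
    context_table: Optional[Path] = None
    species_table: Optional[Path] = None
    hairpin_fasta: Optional[Path] = None
    mature_fasta: Optional[Path] = None

    @staticmethod
    def read_text(path: Path) -> str:
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                return fh.read()
        return path.read_text()

    @classmethod
    def from_dir(cls, directory, version: str = "") -> "ReleaseBundle":
        """Discover the canonical release members inside a directory."""
        d = Path(directory)

        def find(*names):
            for n in names:
                for cand in (d / n, d / (n + ".gz")):
                    if cand.exists():
                        return cand
            return None

        if not version:
            vfile = find("VERSION", "version.txt")
            version = (cls.read_text(vfile).strip() if vfile else "unknown")
        coords = {}
        gdir = d / "genomes"
        if gdir.is_dir():
            for p in sorted(gdir.iterdir()):
                if p.suffix in (".gff", ".gff3") or p.name.endswith(
                        (".gff.gz", ".gff3.gz")):
                    coords[p.name.split(".")[0]] = p
        return cls(
            version=version,
            hairpin_records=find("miRNA.dat", "hairpin.dat"),
            family_file=find("miFam.dat"),
            coordinates=coords,
            context_table=find("context.tsv", "genome_context.tsv"),
            species_table=find("species.tsv", "organisms.tsv"),
            hairpin_fasta=find("hairpin.fa", "hairpin.fasta"),
            mature_fasta=find("mature.fa", "mature.fasta"),
        )


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(bundle: ReleaseBundle, registry=None) -> Dataset:
    """Assemble the full data model from a release bundle.

    Cross-file links are resolved by accession; matures are deduplicated by
    accession across hairpins, which establishes the many-to-many between
    precursors and matures.  Species come from the species table when
    present and are synthesized from name prefixes otherwise.  Seed-family
    and cluster derivation is *not* run here — it is a separate, explicit
    step (:mod:`mirhub.groupings`).
    """
    if bundle.hairpin_records is None:
        raise MirhubError("release bundle has no hairpin record file")
    records = parse_hairpin_records(
        ReleaseBundle.read_text(bundle.hairpin_records))

    ds = Dataset(release_version=bundle.version, registry=registry)

    species_rows = []
    if bundle.species_table is not None:
        species_rows = parse_species_table(
            ReleaseBundle.read_text(bundle.species_table))
    for abbrev, name, division, taxonomy, assembly in species_rows:
        if abbrev not in ds.store("species"):
            ds.add(Species(abbrev, name, division, taxonomy, assembly))

    mature_fa = (parse_fasta_sequences(
        ReleaseBundle.read_text(bundle.mature_fasta))
        if bundle.mature_fasta else {})
    hairpin_fa = (parse_fasta_sequences(
        ReleaseBundle.read_text(bundle.hairpin_fasta))
        if bundle.hairpin_fasta else {})

    acc_to_name: dict = {}
    mature_by_acc: dict = {}
    for rec in records:
        if rec.name in ds.store("precursor"):
            log.warning("duplicate precursor name %r: record skipped",
                        rec.name)
            continue
        prec = Precursor(name=rec.name, accession=rec.accession,
                         description=rec.description, sequence=rec.sequence,
                         comment=rec.comment)
        fa_seq = hairpin_fa.get(rec.accession)
        if fa_seq is not None and fa_seq != rec.sequence:
            log.warning("hairpin FASTA disagrees with record for %s; "
                        "record file wins", rec.accession)
        ds.add(prec)
        acc_to_name[rec.accession] = rec.name

        code = rec.species_code
        if code not in ds.store("species"):
            log.info("synthesizing species %r from name prefix", code)
            ds.add(Species(abbreviation=code, name=code))
        ds.link("species", code, "precursors", rec.name)

        for feat in rec.matures:
            mseq = rec.sequence[feat.start - 1:feat.end]
            existing = mature_by_acc.get(feat.accession)
            if existing is None:
                fa = mature_fa.get(feat.accession)
                if fa is not None and fa != mseq:
                    log.warning("mature FASTA disagrees with record slice "
                                "for %s; record file wins", feat.accession)
                if feat.product in ds.store("mature"):
                    log.warning("mature name %r reused under a second "
                                "accession %s; feature skipped",
                                feat.product, feat.accession)
                    continue
                ds.add(Mature(name=feat.product, accession=feat.accession,
                              evidence=feat.evidence,
                              experiment=feat.experiment,
                              similarity=feat.similarity, sequence=mseq))
                existing = ds.store("mature")[feat.product]
                mature_by_acc[feat.accession] = existing
            elif existing.sequence != mseq:
                log.warning("mature %s has differing sequence under %s; "
                            "first occurrence wins", feat.accession, rec.name)
            ds.link("precursor", rec.name, "matures", existing.name)

        for ref in rec.references:
            if ref.medline not in ds.store("paper"):
                ds.add(Paper(medline=ref.medline, title=ref.title,
                             author=ref.authors, journal=ref.journal))
            ds.link("precursor", rec.name, "papers", ref.medline)

    if bundle.family_file is not None:
        fam_rows = parse_family_file(ReleaseBundle.read_text(
            bundle.family_file))
        for acc, name, member_accs in fam_rows:
            ds.add(PrecursorFamily(name=name, accession=acc))
            for macc in member_accs:
                pname = acc_to_name.get(macc)
                if pname is None:
                    log.warning("family %r member %s unknown; skipped",
                                name, macc)
                    continue
                ds.link("precursor_family", name, "precursors", pname)

    for code, path in sorted(bundle.coordinates.items()):
        rows = parse_coordinates(ReleaseBundle.read_text(path), species=code)
        counters: dict = {}
        for ident, xsome, start, end, strand in rows:
            pname = acc_to_name.get(ident, ident)
            if pname not in ds.store("precursor"):
                log.warning("coordinates for unknown precursor %r skipped",
                            ident)
                continue
            n = counters.get(pname, 0) + 1
            counters[pname] = n
            gp = GenomePosition(identifier=f"{pname}-pos-{n}", xsome=xsome,
                                contig_start=start, contig_end=end,
                                strand=strand)
            ds.add(gp)
            ds.link("precursor", pname, "genome_positions", gp.identifier)

    if bundle.context_table is not None:
        rows = parse_context_table(ReleaseBundle.read_text(
            bundle.context_table))
        counters = {}
        for ident, source, tname, sense, otype in rows:
            pname = acc_to_name.get(ident, ident)
            if pname not in ds.store("precursor"):
                log.warning("context for unknown precursor %r skipped", ident)
                continue
            n = counters.get(pname, 0) + 1
            counters[pname] = n
            gc = GenomeContext(identifier=f"{pname}-ctx-{n}",
                               overlap_sense=sense, overlap_type=otype,
                               transcript_source=source,
                               transcript_name=tname)
            ds.add(gc)
            ds.link("precursor", pname, "genome_contexts", gc.identifier)

    return ds


# ---------------------------------------------------------------------------
# Release fetching (network; never exercised by the test suite)
# ---------------------------------------------------------------------------

MIRBASE_BASE_URL = "https://www.mirbase.org/ftp"

_RELEASE_MEMBERS = ("miRNA.dat.gz", "miFam.dat.gz", "hairpin.fa.gz",
                    "mature.fa.gz")


def fetch_release(version: Optional[str], destination,
                  base_url: str = MIRBASE_BASE_URL) -> ReleaseBundle:
    """Download a release into `destination` and return its bundle.

    `version=None` fetches the CURRENT release.  Already-present files are
    kept (idempotent).  All tests run from locally generated fixtures; this
    is a convenience for users with network access.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    slug = version if version else "CURRENT"
    got_any = False
    for member in _RELEASE_MEMBERS:
        target = dest / member
        if target.exists():
            got_any = True
            continue
        url = f"{base_url}/{slug}/{member}"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                target.write_bytes(resp.read())
            got_any = True
        except Exception as exc:  # noqa: BLE001
            if member == "miRNA.dat.gz":
                raise UnknownVersionError(
                    f"release {slug!r} not found at {url}: {exc}") from exc
            log.warning("optional member %s not fetched: %s", member, exc)
    if not got_any:
        raise FetchError(f"could not fetch any member of release {slug!r}")
    (dest / "VERSION").write_text(slug + "\n")
    return ReleaseBundle.from_dir(dest, version=slug)
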