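"""Example plugin: disease annotations for mature miRNAs.

Modelled on public miRNA-disease association services: a *disease* record
keyed by its Disease Ontology identifier (DOID), and a *disease link*
connecting one mature miRNA to one disease with literature provenance and
reported target genes.  Links are identified by the concatenation
``DOID+mature_name+pubmed_id``.

The shipped data files are synthetic (see ``synthetic_m2d_*.tsv``): they
name matures from the default small fixture release, carry made-up DOIDs
and PubMed ids, and exist purely to exercise the plugin mechanics.
"""

from __future__ import annotations

import logging
from pathlib import Path

from ..model import Dataset
from . import PluginAssociation, PluginManifest, PluginType, _entity_class

log = logging.getLogger(__name__)

_HERE = Path(__file__).parent

DISEASE = PluginType(kind="m2d_disease", plural="m2d_diseases",
                     id_field="doid", fields=("doid", "name"))

LINK = PluginType(kind="m2d_disease_link", plural="m2d_disease_links",
                  id_field="identifier",
                  fields=("identifier", "doid", "mature_name", "pubmed_id",
                          "target_genes"))


def link_identifier(doid: str, mature_name: str, pubmed_id: str) -> str:
    """Composite link key: DOID + mature name + PubMed id."""
    return f"{doid}+{mature_name}+{pubmed_id}"


def load_data(dataset: Dataset, source=None) -> int:
    """Load disease and link tables from `source` (a directory).

    Defaults to the synthetic tables shipped with the plugin.  Links whose
    mature name or DOID does not resolve are skipped and logged.
    """
    src = Path(source) if source is not None else _HERE
    disease_cls = _entity_class(DISEASE)
    link_cls = _entity_class(LINK)
    n = 0

    disease_path = _pick(src, "m2d_diseases.tsv", "synthetic_m2d_diseases.tsv")
    for lineno, cols in _rows(disease_path, 2):
        doid, name = cols
        if doid in dataset.store("m2d_disease"):
            log.warning("duplicate disease %s at line %d skipped",
                        doid, lineno)
            continue
        dataset.add(disease_cls(doid=doid, name=name))
        n += 1

    link_path = _pick(src, "m2d_disease_links.tsv",
                      "synthetic_m2d_disease_links.tsv")
    for lineno, cols in _rows(link_path, 4):
        doid, mature_name, pubmed_id, target_genes = cols
        if mature_name not in dataset.store("mature"):
            log.warning("link at line %d names unknown mature %r; skipped",
                        lineno, mature_name)
            continue
        if doid not in dataset.store("m2d_disease"):
            log.warning("link at line %d names unknown disease %r; skipped",
                        lineno, doid)
            continue
        ident = link_identifier(doid, mature_name, pubmed_id)
        if ident in dataset.store("m2d_disease_link"):
            log.warning("duplicate link %s at line %d skipped", ident, lineno)
            continue
        dataset.add(link_cls(identifier=ident, doid=doid,
                             mature_name=mature_name, pubmed_id=pubmed_id,
                             target_genes=target_genes))
        dataset.link("m2d_disease_link", ident, "m2d_disease", doid)
        dataset.link("m2d_disease_link", ident, "mature", mature_name)
        n += 1
    return n


def _pick(src: Path, *names) -> Path:
    for name in names:
        p = src / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no disease table among {names} in {src}")


def _rows(path: Path, n_cols: int):
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != n_cols:
            log.warning("%s line %d: expected %d columns, got %d",
                        path.name, lineno, n_cols, len(cols))
            continue
        yield lineno, [c.strip() for c in cols]


MANIFEST = PluginManifest(
    name="m2d",
    types=(DISEASE, LINK),
    associations=(
        PluginAssociation("m2d_disease", "m2d_disease_links",
                          "m2d_disease_link", "many",
                          inverse="m2d_disease",
                          inverse_cardinality="one"),
        PluginAssociation("mature", "m2d_disease_links",
                          "m2d_disease_link", "many",
                          inverse="mature",
                          inverse_cardinality="one"),
    ),
    loader=load_data,
    tests_path=str(_HERE / "test_m2d_plugin.py"),
)
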