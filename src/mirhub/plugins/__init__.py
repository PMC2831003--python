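"""Plugin framework: third-party models, associations and routes.

A plugin is a declarative :class:`PluginManifest`: the entity types it
introduces, the associations binding them to core (or other plugin) kinds,
a data loader callable, and a pytest file so plugin behaviour is verified
together with the core suite.  Registration extends a registry in place;
the core surface is never modified — plugins may only *add* kinds, nested
routes on existing members, and data.  Load order is alphabetical by
plugin name and must not matter.

Plugin entity classes are generated dataclasses keyed by the declared
identifier field, so plugin entities flow through ``get_entity``,
``traverse``, the REST layer and dataset snapshots exactly like core ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, make_dataclass
from pathlib import Path
from typing import Callable, Optional

from ..errors import (DanglingAssociationError, PluginCollisionError,
                      PluginError)
from ..model import Association, Dataset, KindInfo, Registry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PluginType:
    """A new entity kind contributed by a plugin."""

    kind: str
    plural: str
    id_field: str
    fields: tuple
    sequence_bearing: bool = False


@dataclass(frozen=True)
class PluginAssociation:
    """A declared association between a plugin kind and an existing kind."""

    source: str
    name: str
    target: str
    cardinality: str              # 'one' | 'many'
    inverse: str
    inverse_cardinality: str


@dataclass(frozen=True)
class PluginManifest:
    """Everything the core needs to integrate a plugin."""

    name: str
    types: tuple
    associations: tuple
    loader: Callable                  # loader(dataset, source) -> int loaded
    tests_path: str                   # pytest file shipped by the plugin

    def entity_class(self, ptype: PluginType):
        return _entity_class(ptype)


_CLASS_CACHE: dict = {}


def _entity_class(ptype: PluginType):
    """Dataclass for a plugin kind, with the same `.kind`/`.id` surface as
    core entities."""
    if ptype in _CLASS_CACHE:
        return _CLASS_CACHE[ptype]
    cls = make_dataclass(
        "".join(part.capitalize() for part in ptype.kind.split("_")),
        [(f, str, "") if f != ptype.id_field else (f, str)
         for f in ptype.fields],
        namespace={
            "kind": ptype.kind,
            "id": property(lambda self, _f=ptype.id_field:
                           getattr(self, _f)),
        })
    _CLASS_CACHE[ptype] = cls
    return cls


def register_plugin(target, manifest: PluginManifest) -> Registry:
    """Register a plugin's kinds and associations into a registry.

    `target` is a :class:`Registry` or a :class:`Dataset` (its registry is
    used).  Collisions with core or previously loaded plugins fail with
    :class:`PluginCollisionError`; associations referencing unknown kinds
    fail with :class:`DanglingAssociationError`; a manifest without a test
    suite is rejected.
    """
    registry = target.registry if isinstance(target, Dataset) else target
    if not manifest.tests_path or not Path(manifest.tests_path).exists():
        raise PluginError(
            f"plugin {manifest.name!r} declares no test suite")
    for ptype in manifest.types:
        if ptype.kind in registry.kinds:
            raise PluginCollisionError(
                f"plugin {manifest.name!r} redeclares kind {ptype.kind!r}")
        if any(k.plural == ptype.plural for k in registry.kinds.values()):
            raise PluginCollisionError(
                f"plugin {manifest.name!r} reuses route segment "
                f"{ptype.plural!r}")
    new_kinds = {t.kind for t in manifest.types}
    for assoc in manifest.associations:
        for endpoint in (assoc.source, assoc.target):
            if endpoint not in registry.kinds and endpoint not in new_kinds:
                raise DanglingAssociationError(
                    f"plugin {manifest.name!r} association "
                    f"{assoc.source}.{assoc.name} references unknown kind "
                    f"{endpoint!r}")
        if (assoc.source, assoc.name) in registry.associations:
            raise PluginCollisionError(
                f"plugin {manifest.name!r} redeclares association "
                f"{assoc.source}.{assoc.name}")

    for ptype in manifest.types:
        registry.register_kind(KindInfo(
            ptype.kind, ptype.plural, ptype.id_field, ptype.fields,
            sequence_bearing=ptype.sequence_bearing,
            factory=_entity_class(ptype), origin=manifest.name))
    for assoc in manifest.associations:
        registry.register_association(Association(
            assoc.source, assoc.name, assoc.target, assoc.cardinality,
            inverse=assoc.inverse, origin=manifest.name))
        registry.register_association(Association(
            assoc.target, assoc.inverse, assoc.source,
            assoc.inverse_cardinality, inverse=assoc.name,
            origin=manifest.name))
    log.info("registered plugin %s (%d kinds, %d associations)",
             manifest.name, len(manifest.types), len(manifest.associations))
    return registry


def register_plugins(target, manifests) -> Registry:
    """Register several plugins in alphabetical order by name."""
    registry = target.registry if isinstance(target, Dataset) else target
    for manifest in sorted(manifests, key=lambda m: m.name):
        register_plugin(registry, manifest)
    return registry


def load_plugin_data(dataset: Dataset, manifest: PluginManifest,
                     source=None) -> int:
    """Run the plugin's loader; returns the number of entities loaded."""
    return manifest.loader(dataset, source)


def builtin_plugins() -> dict:
    """Name -> manifest for the plugins shipped with the package."""
    from .m2d import MANIFEST as m2d_manifest
    return {m2d_manifest.name: m2d_manifest}
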