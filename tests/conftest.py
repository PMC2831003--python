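import pytest

from mirhub.fixtures import FixtureSpec, generate_release
from mirhub.groupings import build_precursor_clusters, build_seed_families
from mirhub.ingest import build_dataset
from mirhub.plugins import load_plugin_data, register_plugin
from mirhub.plugins.m2d import MANIFEST as M2D_MANIFEST
from mirhub.rest import Service


@pytest.fixture(scope="session")
def small_release(tmp_path_factory):
    """Default synthetic release (bundle, manifest), generated once."""
    dest = tmp_path_factory.mktemp("release-small")
    return generate_release(FixtureSpec(seed=42), dest)


@pytest.fixture()
def dataset(small_release):
    """A freshly ingested dataset (function-scoped: tests may mutate it)."""
    bundle, _ = small_release
    return build_dataset(bundle)


@pytest.fixture()
def manifest(small_release):
    return small_release[1]


@pytest.fixture(scope="session")
def full_service(small_release):
    """Dataset with derivations and the disease plugin, behind a Service.

    Session-scoped and read-only: tests must not mutate it.
    """
    bundle, manifest = small_release
    ds = build_dataset(bundle)
    build_seed_families(ds, 6)
    build_seed_families(ds, 7)
    build_precursor_clusters(ds, manifest.cluster_params)
    register_plugin(ds, M2D_MANIFEST)
    load_plugin_data(ds, M2D_MANIFEST)
    return Service(ds)
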