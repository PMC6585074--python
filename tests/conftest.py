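import pytest

from anatomykg import (
    BuilderContext,
    IriMinter,
    QuadStore,
    paper_example,
)
from anatomykg.fixtures import FixtureConfig, generate_description


@pytest.fixture(scope="session")
def paper_store():
    """The fixed worked example (session-scoped; treated as read-only)."""
    store, doc = paper_example()
    return store, doc


@pytest.fixture()
def ctx():
    """A fresh builder context bound to a fresh store's catalogs."""
    store = QuadStore()
    return BuilderContext(
        IriMinter("https://test.example/", 7),
        store.predicates,
        store.terms,
        store.ng_classes,
    )


@pytest.fixture(scope="session")
def generated():
    """One mid-sized generated description with its ground truth."""
    return generate_description(FixtureConfig(seed=11, n_parts=9, n_specimens=3))


def oracle_find_graphs(store, pattern):
    """Brute-force scan over all quads: the independent reference for every
    pattern/locate/union operation."""
    hits = set()
    for q in store.quads():
        if pattern.matches(q.statement):
            hits.add(q.graph)
    return sorted(hits)


def oracle_union(store, iris):
    out = set()
    wanted = set(iris)
    for q in store.quads():
        if q.graph in wanted:
            out.add(q.statement)
    return out
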