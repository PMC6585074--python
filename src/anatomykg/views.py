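"""Data views: named selections of named-graph classes.

A view names a set of named-graph class keys (plus an optional unit filter)
and resolves, for a document, to the union of the document's description
graphs of those classes. First-level views name a single class (e.g. the
parthood view); combined views name several (e.g. a general-measurements view
over every measurement class); filtered views additionally constrain the
measurement unit (e.g. a lengths-and-distances view over metre-based units
only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .core import Iri, Statement, TermRef
from .errors import CatalogError, RegistryError
from .store import (
    QuadStore,
    locate_assertions_graph,
    locate_document_graph,
    locate_instance_anatomy,
)

__all__ = [
    "DataView",
    "ViewRegistry",
    "metre_based",
    "resolve_view",
    "resolve_view_multi",
    "default_views",
    "METRE_BASED_UNIT_LABELS",
]

#: UO labels counted as metre-based; configuration, not a closed list.
METRE_BASED_UNIT_LABELS = ("meter", "centimeter", "millimeter", "micrometer")


def metre_based(unit: TermRef) -> bool:
    """Unit filter selecting metre-based length units."""
    return unit.prefix == "uo" and unit.label in METRE_BASED_UNIT_LABELS


#: named unit filters usable from serialized view definitions
NAMED_UNIT_FILTERS: dict[str, Callable[[TermRef], bool]] = {
    "metre-based": metre_based,
}


@dataclass(frozen=True)
class DataView:
    name: str
    ng_classes: frozenset[str]
    unit_filter: Optional[Callable[[TermRef], bool]] = None
    description: str = ""


class ViewRegistry:
    """Registry of named data views, so users can invoke views by name
    without knowing the query language behind them."""

    def __init__(self, ng_catalog_keys: Iterable[str]):
        self._known_keys = set(ng_catalog_keys)
        self._views: dict[str, DataView] = {}

    def define_view(
        self,
        name: str,
        ng_classes: Iterable[str],
        unit_filter: Optional[Callable[[TermRef], bool]] = None,
        description: str = "",
    ) -> DataView:
        classes = frozenset(ng_classes)
        if not classes:
            raise CatalogError("a data view needs at least one named-graph class")
        unknown = classes - self._known_keys
        if unknown:
            raise CatalogError(f"unknown named-graph class keys: {sorted(unknown)}")
        if name in self._views:
            raise RegistryError(f"a view named {name!r} is already registered")
        view = DataView(name, classes, unit_filter, description)
        self._views[name] = view
        return view

    def get(self, name: str) -> DataView:
        try:
            return self._views[name]
        except KeyError:
            raise CatalogError(f"no view named {name!r}")

    def names(self) -> list[str]:
        return sorted(self._views)


def default_views(store: QuadStore) -> ViewRegistry:
    """The stock views: one first-level view per named-graph class, plus the
    combined general-measurements view and the metre-filtered
    lengths-and-distances view."""
    reg = ViewRegistry(store.ng_classes.keys())
    for key in store.ng_classes.keys():
        if store.ng_classes.scheme(key).kind in ("parthood", "quality", "measurement"):
            reg.define_view(f"{key}-view", {key}, description=f"first-level view over {key}")
    measurement_keys = store.ng_classes.keys_of_kind("measurement")
    reg.define_view("general-measurements", measurement_keys,
                    description="every measurement named-graph class")
    reg.define_view("lengths-and-distances", measurement_keys, metre_based,
                    description="metre-based measurements only")
    return reg


def _graph_unit_terms(store: QuadStore, graph_iri: Iri) -> list[TermRef]:
    g = store.get_graph(graph_iri)
    p = store.predicates
    unit_nodes = {st.o for st in g.statements if st.p == p.has_unit and isinstance(st.o, Iri)}
    terms = []
    for st in g.statements:
        if st.p == p.rdf_type and st.s in unit_nodes and isinstance(st.o, Iri):
            term = store.terms.by_iri(st.o)
            if term is not None:
                terms.append(term)
    return terms


def resolve_view(store: QuadStore, document: Iri, view: DataView) -> set[Statement]:
    """Union of the document's description graphs matched by the view."""
    doc_graph = locate_document_graph(store, document)
    assertions = locate_assertions_graph(store, doc_graph)
    anatomy = locate_instance_anatomy(store, assertions)
    p = store.predicates
    ag = store.get_graph(assertions)
    wanted_cls = {store.ng_classes.term(k).iri for k in view.ng_classes}
    out: set[Statement] = set()
    for st in sorted(ag.statements):
        if st.s != anatomy or st.p != p.has_part or not isinstance(st.o, Iri):
            continue
        if st.o not in store:
            continue
        g = store.get_graph(st.o)
        if g.ng_class.iri not in wanted_cls:
            continue
        if view.unit_filter is not None:
            units = _graph_unit_terms(store, g.iri)
            if not units or not all(view.unit_filter(u) for u in units):
                continue
        out |= g.statements
    return out


def resolve_view_multi(store: QuadStore, documents: Iterable[Iri], view: DataView) -> set[Statement]:
    """Union of per-document resolutions over a set of documents."""
    out: set[Statement] = set()
    for doc in documents:
        out |= resolve_view(store, doc, view)
    return out
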