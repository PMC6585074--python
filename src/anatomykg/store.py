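"""Quad storage and the query templates over it.

The store keeps one :class:`~anatomykg.core.NamedGraph` per graph IRI and
answers triple-pattern queries over the resulting quads. The locate/union
operations mirror the standard SPARQL templates for this data model:

* find the document graph from the document individual's type triple;
* find the assertions graph registered inside the document graph;
* find the instance-anatomy individual inside the assertions graph;
* union the named graphs the instance anatomy (or the methods section) has as
  parts, optionally filtered by named-graph class.

All list-valued results are returned in lexicographic IRI order so that every
operation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import networkx as nx

from .core import (
    Iri,
    Literal,
    NamedGraph,
    NamedGraphClassCatalog,
    PredicateTable,
    Quad,
    Statement,
    TermCatalog,
    default_ng_catalog,
    default_term_catalog,
)
from .errors import (
    AmbiguityError,
    CollisionError,
    ConfigurationError,
    CycleError,
    DanglingReferenceError,
    MalformedPartonomyError,
    NotFoundError,
)

__all__ = [
    "QuadStore",
    "TriplePattern",
    "Partonomy",
    "locate_document_graph",
    "locate_assertions_graph",
    "locate_instance_anatomy",
    "union_graphs",
    "parthood_union",
    "description_union",
    "metadata_union",
    "extract_partonomy",
]


@dataclass(frozen=True)
class TriplePattern:
    """A triple pattern; ``None`` is the wildcard. At least one position must
    be bound."""

    s: Optional[Iri] = None
    p: Optional[Iri] = None
    o: Optional[Union[Iri, Literal]] = None

    def __post_init__(self) -> None:
        if self.s is None and self.p is None and self.o is None:
            raise ConfigurationError("a triple pattern needs at least one bound position")

    def matches(self, st: Statement) -> bool:
        return (
            (self.s is None or st.s == self.s)
            and (self.p is None or st.p == self.p)
            and (self.o is None or st.o == self.o)
        )


class QuadStore:
    """The collection of named graphs for one or more description documents."""

    def __init__(
        self,
        predicates: Optional[PredicateTable] = None,
        ng_classes: Optional[NamedGraphClassCatalog] = None,
        terms: Optional[TermCatalog] = None,
    ) -> None:
        self._graphs: dict[Iri, NamedGraph] = {}
        self.predicates = predicates or PredicateTable()
        self.ng_classes = ng_classes or default_ng_catalog()
        self.terms = terms or default_term_catalog()

    # -- storage ------------------------------------------------------------

    def add_graph(self, g: NamedGraph, replace: bool = False) -> "QuadStore":
        if g.iri in self._graphs and not replace:
            raise CollisionError(f"graph IRI already in store: {g.iri}")
        self._graphs[g.iri] = g
        return self

    def add_graphs(self, graphs) -> "QuadStore":
        for g in graphs:
            self.add_graph(g)
        return self

    def get_graph(self, iri: Iri) -> NamedGraph:
        try:
            return self._graphs[iri]
        except KeyError:
            raise DanglingReferenceError(f"no such graph in store: {iri}")

    def __contains__(self, iri: Iri) -> bool:
        return iri in self._graphs

    def __len__(self) -> int:
        return len(self._graphs)

    def graphs(self) -> list[NamedGraph]:
        return [self._graphs[i] for i in sorted(self._graphs)]

    def graph_iris(self) -> list[Iri]:
        return sorted(self._graphs)

    def quads(self) -> Iterator[Quad]:
        for g in self.graphs():
            yield from g.quads()

    def quad_count(self) -> int:
        return sum(len(g) for g in self._graphs.values())

    # -- pattern queries ----------------------------------------------------

    def find_graphs_containing(self, pattern: TriplePattern) -> list[Iri]:
        """All graph IRIs whose statement set matches the pattern, in
        lexicographic order."""
        hits = [
            g.iri
            for g in self._graphs.values()
            if any(pattern.matches(st) for st in g.statements)
        ]
        return sorted(hits)

    def match(self, pattern: TriplePattern, graph: Optional[Iri] = None) -> list[Statement]:
        """Statements matching the pattern, within one graph or store-wide."""
        graphs = [self.get_graph(graph)] if graph is not None else self.graphs()
        out = {st for g in graphs for st in g.statements if pattern.matches(st)}
        return sorted(out)


# ---------------------------------------------------------------------------
# Locate templates (the two-/three-step lookups)


def _unique(iris: list[Iri], what: str) -> Iri:
    if not iris:
        raise NotFoundError(f"no {what} found")
    if len(iris) > 1:
        raise AmbiguityError(f"{what} is ambiguous: {[i.value for i in iris]}")
    return iris[0]


def locate_document_graph(store: QuadStore, doc: Iri) -> Iri:
    """The unique graph containing ``(doc, rdf:type, iao:document)``."""
    doc_class = store.terms.get("iao", "document").iri
    pattern = TriplePattern(doc, store.predicates.rdf_type, doc_class)
    return _unique(store.find_graphs_containing(pattern), f"document graph for {doc}")


def locate_assertions_graph(store: QuadStore, document_graph: Iri) -> Iri:
    """The IRI typed as an assertions named graph inside the document graph."""
    g = store.get_graph(document_graph)
    cls = store.ng_classes.term("assertions").iri
    p = store.predicates
    hits = sorted(
        st.s for st in g.statements if st.p == p.rdf_type and st.o == cls
    )
    return _unique(hits, "assertions named graph")


def locate_instance_anatomy(store: QuadStore, assertions_graph: Iri) -> Iri:
    """The individual typed 'instance anatomy' inside the assertions graph."""
    g = store.get_graph(assertions_graph)
    cls = store.terms.get("ngo", "instance anatomy").iri
    p = store.predicates
    hits = sorted(
        st.s for st in g.statements if st.p == p.rdf_type and st.o == cls
    )
    return _unique(hits, "instance anatomy")


# ---------------------------------------------------------------------------
# Unions


def union_graphs(store: QuadStore, iris) -> set[Statement]:
    """Set-union of the statements of the given graphs. Duplicates collapse
    and graph provenance is dropped — that is the point of the union."""
    out: set[Statement] = set()
    for iri in iris:
        out |= store.get_graph(iri).statements
    return out


def _graphs_part_of(store: QuadStore, whole: Iri, assertions_graph: Iri) -> list[Iri]:
    g = store.get_graph(assertions_graph)
    p = store.predicates
    parts = {
        st.o for st in g.statements if st.s == whole and st.p == p.has_part
    }
    return sorted(i for i in parts if isinstance(i, Iri))


def parthood_union(store: QuadStore, anatomy: Iri, assertions_graph: Iri) -> set[Statement]:
    """Union of exactly the parthood named graphs of the given instance
    anatomy: graphs g with (anatomy, has part, g) and (g, rdf:type, parthood
    named graph class) in the assertions graph."""
    g = store.get_graph(assertions_graph)
    p = store.predicates
    parthood_cls = store.ng_classes.term("parthood").iri
    candidates = _graphs_part_of(store, anatomy, assertions_graph)
    typed = {
        st.s
        for st in g.statements
        if st.p == p.rdf_type and st.o == parthood_cls
    }
    return union_graphs(store, [i for i in candidates if i in typed])


def description_union(store: QuadStore, anatomy: Iri, assertions_graph: Iri) -> set[Statement]:
    """Union of *all* named graphs the instance anatomy has as parts — the
    Anatomy Knowledge Graph of the document."""
    return union_graphs(store, _graphs_part_of(store, anatomy, assertions_graph))


def metadata_union(store: QuadStore, methods_section: Iri, assertions_graph: Iri) -> set[Statement]:
    """Union of the metadata named graphs the methods section has as parts."""
    return union_graphs(store, _graphs_part_of(store, methods_section, assertions_graph))


# ---------------------------------------------------------------------------
# Partonomy extraction


@dataclass
class Partonomy:
    """The parthood backbone of a description: a rooted tree (or DAG with a
    warning elsewhere) over part-instance IRIs, plus their labels and class
    affiliations."""

    root: Iri
    edges: set[tuple[Iri, Iri]]
    labels: dict[Iri, str] = field(default_factory=dict)
    classes: dict[Iri, Iri] = field(default_factory=dict)

    @property
    def nodes(self) -> set[Iri]:
        out = {self.root}
        for a, b in self.edges:
            out |= {a, b}
        return out

    def parent_map(self) -> dict[Iri, Iri]:
        return {child: parent for parent, child in self.edges}

    def depth(self) -> int:
        """Number of levels (a lone root is depth 1)."""
        if not self.edges:
            return 1
        dg = nx.DiGraph(list((a.value, b.value) for a, b in self.edges))
        return 1 + max(
            nx.shortest_path_length(dg, self.root.value, n) for n in dg.nodes
        )


def extract_partonomy(
    statements: set[Statement],
    predicates: Optional[PredicateTable] = None,
) -> Partonomy:
    """Recover the partonomy from a parthood-union statement set.

    The root is the unique part instance with no incoming ``has part`` edge;
    edges come from the ``has part`` statements, labels and class affiliations
    from ``rdfs:label`` / ``rdf:type``.
    """
    p = predicates or PredicateTable()
    edges: set[tuple[Iri, Iri]] = set()
    labels: dict[Iri, str] = {}
    classes: dict[Iri, Iri] = {}
    nodes: set[Iri] = set()
    for st in statements:
        if st.p == p.has_part and isinstance(st.o, Iri):
            edges.add((st.s, st.o))
            nodes |= {st.s, st.o}
        elif st.p == p.rdfs_label and isinstance(st.o, Literal):
            labels[st.s] = st.o.lexical
            nodes.add(st.s)
        elif st.p == p.rdf_type and isinstance(st.o, Iri):
            classes[st.s] = st.o
            nodes.add(st.s)
    if not nodes:
        raise MalformedPartonomyError("no part instances in the statement set")
    dg = nx.DiGraph()
    dg.add_nodes_from(n.value for n in nodes)
    dg.add_edges_from((a.value, b.value) for a, b in edges)
    if not nx.is_directed_acyclic_graph(dg):
        raise CycleError("parthood statements contain a cycle")
    roots = sorted(n for n, deg in dg.in_degree() if deg == 0)
    if len(roots) != 1:
        raise MalformedPartonomyError(
            f"expected exactly one partonomy root, found {len(roots)}: {roots}"
        )
    return Partonomy(Iri(roots[0]), edges, labels, classes)
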