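"""Builders for every class of named graph.

Each builder emits exactly the statements its graph class's data scheme
mandates — one descriptive statement (one parthood edge, one quality, one
measurement) or one metadata record per graph. Keeping the graphs minimal is
deliberate: a part's type and label are asserted only in its parthood graph,
and quality/measurement graphs refer to the bearer by IRI alone, so the union
of any subset of graphs reconnects through shared instance IRIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .core import (
    Instance,
    Iri,
    IriMinter,
    Literal,
    NamedGraph,
    NamedGraphClassCatalog,
    PredicateTable,
    Statement,
    TermCatalog,
    TermRef,
    default_ng_catalog,
    default_term_catalog,
)
from .errors import CatalogError, CycleError, HistoryError, IntegrityError, SchemeError

__all__ = [
    "BuilderContext",
    "DocumentMetadata",
    "DocumentGraphResult",
    "MeasurementRecord",
    "QualityRecord",
    "AssayRecord",
    "CollectionRecord",
    "ProcessingStep",
    "SECTION_KEYS",
    "REQUIRED_SECTION_KEYS",
    "build_document_graph",
    "build_root_parthood_graph",
    "build_parthood_graph",
    "build_quality_graph",
    "build_measurement_graph",
    "build_assay_graph",
    "build_collection_graph",
    "build_history_graph",
    "build_assertions_graph",
]

#: document section keys in publication order, mapped to IAO class labels
SECTION_KEYS: tuple[tuple[str, str], ...] = (
    ("abstract", "abstract"),
    ("author-list", "author list"),
    ("introduction", "introduction"),
    ("methods", "methods section"),
    ("results", "results section"),
    ("discussion", "discussion section"),
    ("conclusion", "conclusion section"),
    ("references", "references section"),
)
REQUIRED_SECTION_KEYS = ("methods", "results")
_SECTION_LABELS = dict(SECTION_KEYS)


@dataclass
class BuilderContext:
    """Shared configuration threaded through all builders: the predicate
    table, both catalogs, and the IRI minter."""

    minter: IriMinter
    predicates: PredicateTable = field(default_factory=PredicateTable)
    terms: TermCatalog = field(default_factory=default_term_catalog)
    ng_classes: NamedGraphClassCatalog = field(default_factory=default_ng_catalog)

    def new_instance(self, class_ref: TermRef, label: Optional[str] = None) -> Instance:
        from .core import make_instance

        return make_instance(class_ref, label, self.minter, self.terms)

    def _graph(self, key: str, statements) -> NamedGraph:
        return NamedGraph(self.minter.mint(key), self.ng_classes.term(key), frozenset(statements))


def _st(s: Iri, p: Iri, o) -> Statement:
    return Statement(s, p, o)


# ---------------------------------------------------------------------------
# Record types


@dataclass
class DocumentMetadata:
    """Title plus free text per publication section. The methods and results
    keys must always be present (their text may be empty/None) because those
    two sections anchor the metadata and description layers."""

    title: str
    sections: dict[str, Optional[str]] = field(
        default_factory=lambda: {k: None for k, _ in SECTION_KEYS}
    )

    def validate(self) -> None:
        for key in REQUIRED_SECTION_KEYS:
            if key not in self.sections:
                raise SchemeError(f"document metadata lacks the {key!r} section key")
        unknown = set(self.sections) - set(_SECTION_LABELS)
        if unknown:
            raise SchemeError(f"unknown section keys: {sorted(unknown)}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured quality of one anatomical entity: bearer, PATO quality
    class, float value, UO unit, and the catalog key of the measurement
    named-graph class the record belongs to."""

    bearer: Instance
    quality_class: TermRef
    value: float
    unit: TermRef
    category: str = "anatomical-structure-volume"


@dataclass(frozen=True)
class QualityRecord:
    """One non-measured quality (e.g. a surface texture) of one bearer."""

    bearer: Instance
    quality_class: TermRef
    category: str = "anatomical-surface-texture"


@dataclass
class AssayRecord:
    """An observation process: a specimen in, description graphs out, plus
    who/where/when/how context."""

    assay: Instance
    input_specimen: Instance
    output_graphs: list[Iri]
    agent: Optional[Instance] = None
    device: Optional[Instance] = None
    protocol: Optional[Instance] = None
    place: Optional[Instance] = None
    date: Optional[str] = None
    extra_inputs: list[Instance] = field(default_factory=list)


@dataclass
class CollectionRecord:
    """A specimen collection process: one material entity in, one specimen
    out, plus who/where/when/how context."""

    process: Instance
    input_material: Instance
    output_specimen: Instance
    agent: Optional[Instance] = None
    device: Optional[Instance] = None
    protocol: Optional[Instance] = None
    place: Optional[Instance] = None
    date: Optional[str] = None


@dataclass(frozen=True)
class ProcessingStep:
    """One material-processing step in a specimen history. A step with two or
    more outputs forks the history (e.g. a tissue sample plus a voucher)."""

    process: Instance
    inputs: tuple[Instance, ...]
    outputs: tuple[Instance, ...]

    def __post_init__(self) -> None:
        if not self.inputs or not self.outputs:
            raise SchemeError("a processing step needs at least one input and one output")


# ---------------------------------------------------------------------------
# Builders


@dataclass(frozen=True)
class DocumentGraphResult:
    """A built document graph plus the minted section instances, keyed by
    section key, so callers can wire the assertions graph to the results and
    methods sections."""

    graph: NamedGraph
    document: Instance
    sections: dict[str, Instance]


def build_document_graph(
    meta: DocumentMetadata,
    doc: Instance,
    assertions_iri: Iri,
    ctx: BuilderContext,
) -> DocumentGraphResult:
    """Build the document named graph.

    The graph types the document individual, attaches one typed section
    individual per section key via ``has_part``, records free text for
    sections that have any, and registers the assertions graph (its type
    triple plus a link from the document) so the two-step lookup
    document → assertions graph needs nothing outside this graph.
    """
    meta.validate()
    p = ctx.predicates
    stmts: set[Statement] = {_st(doc.iri, p.rdf_type, ctx.terms.get("iao", "document").iri)}
    sections: dict[str, Instance] = {}
    for key, iao_label in SECTION_KEYS:
        if key not in meta.sections:
            continue
        sec = ctx.new_instance(ctx.terms.get("iao", iao_label), f"{iao_label} of {meta.title}")
        sections[key] = sec
        stmts.add(_st(sec.iri, p.rdf_type, sec.class_ref.iri))
        stmts.add(_st(doc.iri, p.has_part, sec.iri))
        text = meta.sections[key]
        if text:
            stmts.add(_st(sec.iri, p.has_text, Literal(text)))
    stmts.add(_st(assertions_iri, p.rdf_type, ctx.ng_classes.term("assertions").iri))
    stmts.add(_st(doc.iri, p.has_assertions_graph, assertions_iri))
    return DocumentGraphResult(ctx._graph("document", stmts), doc, sections)


def build_root_parthood_graph(root: Instance, ctx: BuilderContext) -> NamedGraph:
    """Parthood graph for the partonomy root: its class affiliation and its
    human-readable label, nothing else (the root has no parent edge)."""
    if not root.label:
        raise SchemeError("the partonomy root must carry a human-readable label")
    p = ctx.predicates
    stmts = {
        _st(root.iri, p.rdf_type, root.class_ref.iri),
        _st(root.iri, p.rdfs_label, Literal(root.label)),
    }
    return ctx._graph("parthood", stmts)


def build_parthood_graph(parent: Instance, child: Instance, ctx: BuilderContext) -> NamedGraph:
    """Parthood graph for a non-root part: the child's type and label plus the
    single ``has part`` edge from its direct parent."""
    if parent.iri == child.iri:
        raise CycleError(f"self-parthood: {child.iri}")
    if not child.label:
        raise SchemeError("every described part must carry a human-readable label")
    p = ctx.predicates
    stmts = {
        _st(child.iri, p.rdf_type, child.class_ref.iri),
        _st(child.iri, p.rdfs_label, Literal(child.label)),
        _st(parent.iri, p.has_part, child.iri),
    }
    return ctx._graph("parthood", stmts)


def build_quality_graph(rec: QualityRecord, ctx: BuilderContext) -> NamedGraph:
    """Quality graph: a freshly minted quality individual typed by a PATO
    subclass, attached to the bearer. Two statements."""
    if rec.category not in ctx.ng_classes:
        raise CatalogError(f"quality category not registered: {rec.category!r}")
    scheme = ctx.ng_classes.scheme(rec.category)
    if scheme.kind != "quality":
        raise CatalogError(f"{rec.category!r} is not a quality named-graph class")
    want = scheme.param("quality_prefix")
    if want and rec.quality_class.prefix != want:
        raise SchemeError(
            f"quality class {rec.quality_class.label!r} is not from the "
            f"{want!r} quality family required by {rec.category!r}"
        )
    p = ctx.predicates
    q = ctx.new_instance(rec.quality_class)
    stmts = {
        _st(rec.bearer.iri, p.has_quality, q.iri),
        _st(q.iri, p.rdf_type, rec.quality_class.iri),
    }
    return ctx._graph(rec.category, stmts)


def build_measurement_graph(rec: MeasurementRecord, ctx: BuilderContext) -> NamedGraph:
    """Measurement graph: the five-statement shape — bearer→quality, quality
    type, float value, unit individual and its class."""
    if not math.isfinite(rec.value):
        raise SchemeError("measurement values must be finite floats")
    if rec.category not in ctx.ng_classes:
        raise CatalogError(f"measurement category not registered: {rec.category!r}")
    if ctx.ng_classes.scheme(rec.category).kind != "measurement":
        raise CatalogError(f"{rec.category!r} is not a measurement named-graph class")
    p = ctx.predicates
    q = ctx.new_instance(rec.quality_class)
    u = ctx.new_instance(rec.unit)
    stmts = {
        _st(rec.bearer.iri, p.has_quality, q.iri),
        _st(q.iri, p.rdf_type, rec.quality_class.iri),
        _st(q.iri, p.has_value, Literal.of_float(rec.value)),
        _st(q.iri, p.has_unit, u.iri),
        _st(u.iri, p.rdf_type, rec.unit.iri),
    }
    return ctx._graph(rec.category, stmts)


def _process_context(stmts: set[Statement], subject: Iri, rec, p: PredicateTable) -> None:
    # who / with what / following what / where / when
    for pred, inst in (
        (p.agent, rec.agent),
        (p.device, rec.device),
        (p.protocol, rec.protocol),
        (p.place, rec.place),
    ):
        if inst is not None:
            stmts.add(_st(inst.iri, p.rdf_type, inst.class_ref.iri))
            stmts.add(_st(subject, pred, inst.iri))
            if inst.label:
                stmts.add(_st(inst.iri, p.rdfs_label, Literal(inst.label)))
    if rec.date is not None:
        stmts.add(_st(subject, p.date, Literal.of_date(rec.date)))


def build_assay_graph(rec: AssayRecord, ctx: BuilderContext) -> NamedGraph:
    """Assay-data graph: the assay individual, its specified input specimen,
    one specified-output link per description graph it grounds, and optional
    agent/device/protocol/place/date context. Extra substance inputs are typed
    in-graph (the specimen itself is typed by the specimen metadata graphs)."""
    if not rec.output_graphs:
        raise SchemeError("an assay must specify at least one output graph")
    p = ctx.predicates
    a = rec.assay.iri
    stmts = {
        _st(a, p.rdf_type, rec.assay.class_ref.iri),
        _st(a, p.has_specified_input, rec.input_specimen.iri),
    }
    for g in rec.output_graphs:
        stmts.add(_st(a, p.has_specified_output, g))
    for extra in rec.extra_inputs:
        stmts.add(_st(extra.iri, p.rdf_type, extra.class_ref.iri))
        stmts.add(_st(a, p.has_specified_input, extra.iri))
    _process_context(stmts, a, rec, p)
    return ctx._graph("assay-data", stmts)


def build_collection_graph(rec: CollectionRecord, ctx: BuilderContext) -> NamedGraph:
    """Specimen-collection graph: one material entity in, one specimen out.
    Input and output are typed here because no other graph types them."""
    c = rec.process.iri
    p = ctx.predicates
    stmts = {
        _st(c, p.rdf_type, rec.process.class_ref.iri),
        _st(rec.input_material.iri, p.rdf_type, rec.input_material.class_ref.iri),
        _st(c, p.has_specified_input, rec.input_material.iri),
        _st(rec.output_specimen.iri, p.rdf_type, rec.output_specimen.class_ref.iri),
        _st(c, p.has_specified_output, rec.output_specimen.iri),
    }
    _process_context(stmts, c, rec, p)
    return ctx._graph("specimen-collection", stmts)


def build_history_graph(steps: Sequence[ProcessingStep], ctx: BuilderContext) -> NamedGraph:
    """Specimen-history graph: the DAG of specimens derived from an initially
    collected specimen through material-processing steps (forks allowed)."""
    if not steps:
        raise HistoryError("a specimen history needs at least one processing step")
    dag = nx.DiGraph()
    for step in steps:
        for i in step.inputs:
            for o in step.outputs:
                dag.add_edge(i.iri, o.iri)
    if not nx.is_directed_acyclic_graph(dag):
        raise CycleError("specimen history contains a cycle")
    p = ctx.predicates
    stmts: set[Statement] = set()
    specimens: dict[Iri, Instance] = {}
    for step in steps:
        stmts.add(_st(step.process.iri, p.rdf_type, step.process.class_ref.iri))
        for i in step.inputs:
            specimens[i.iri] = i
            stmts.add(_st(step.process.iri, p.has_specified_input, i.iri))
        for o in step.outputs:
            specimens[o.iri] = o
            stmts.add(_st(step.process.iri, p.has_specified_output, o.iri))
    for inst in specimens.values():
        stmts.add(_st(inst.iri, p.rdf_type, inst.class_ref.iri))
        if inst.label:
            stmts.add(_st(inst.iri, p.rdfs_label, Literal(inst.label)))
    return ctx._graph("specimen-history", stmts)


def build_assertions_graph(
    results_section: Instance,
    methods_section: Instance,
    anatomy: Instance,
    description_graphs: Sequence[NamedGraph],
    metadata_graphs: Sequence[NamedGraph],
    ctx: BuilderContext,
    graph_iri: Optional[Iri] = None,
) -> NamedGraph:
    """Assertions graph tying the three layers together.

    The results section has the instance anatomy as a part; the instance
    anatomy has every description named graph as a part; the methods section
    has every metadata named graph as a part. Each referenced graph IRI is
    typed here by its named-graph class, which is what the union query
    templates filter on.

    ``graph_iri`` lets the caller pre-mint the assertions graph's IRI (it must
    already be registered in the document graph); a fresh IRI is minted when
    omitted.
    """
    desc_iris = [g.iri for g in description_graphs]
    meta_iris = [g.iri for g in metadata_graphs]
    dupes = set(desc_iris) & set(meta_iris)
    if dupes:
        raise IntegrityError(
            f"graphs listed as both description and metadata: {sorted(i.value for i in dupes)}"
        )
    p = ctx.predicates
    stmts = {
        _st(results_section.iri, p.has_part, anatomy.iri),
        _st(anatomy.iri, p.rdf_type, anatomy.class_ref.iri),
    }
    for g in description_graphs:
        stmts.add(_st(anatomy.iri, p.has_part, g.iri))
        stmts.add(_st(g.iri, p.rdf_type, g.ng_class.iri))
    for m in metadata_graphs:
        stmts.add(_st(methods_section.iri, p.has_part, m.iri))
        stmts.add(_st(m.iri, p.rdf_type, m.ng_class.iri))
    iri = graph_iri if graph_iri is not None else ctx.minter.mint("assertions")
    return NamedGraph(iri, ctx.ng_classes.term("assertions"), frozenset(stmts))
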