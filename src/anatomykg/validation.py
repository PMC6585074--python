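"""Scheme conformance and referential integrity.

Every named-graph class carries exactly one data scheme — the "data standard"
that makes graphs of the same class comparable across descriptions. Schemes
are interpreted from the declarative :class:`~anatomykg.core.SchemeSpec` in
the named-graph-class catalog, so registering a new class (say a colour
quality category) needs no new validation code.

Two levels of checking:

* :func:`validate_named_graph` — does one graph match its class's shape?
  Shapes are closed: a statement the scheme cannot account for is an error,
  which is what gives single-statement mutations no place to hide.
* :func:`validate_document` — cross-graph integrity: every referenced graph
  resolves, assay outputs are description graphs of the anatomy, the
  partonomy has one root and no cycles, and every graph is individually
  valid.

Severities: structural breakage is an ``error``; things the model tolerates
(a part with several parents, a description graph with no recorded assay, a
quality bearer outside the partonomy) are ``warning``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .core import (
    Iri,
    Literal,
    NamedGraph,
    NamedGraphClassCatalog,
    PredicateTable,
    Statement,
    TermCatalog,
    XSD_FLOAT,
    default_ng_catalog,
    default_term_catalog,
)
from .builders import SECTION_KEYS, REQUIRED_SECTION_KEYS
from .errors import CatalogError
from .store import QuadStore, locate_assertions_graph, locate_document_graph, locate_instance_anatomy
from .errors import AmbiguityError, CycleError, MalformedPartonomyError, NotFoundError

__all__ = [
    "Violation",
    "ValidationReport",
    "ValidationContext",
    "validate_named_graph",
    "validate_document",
    "required_statements",
]


@dataclass(frozen=True)
class Violation:
    graph: Optional[Iri]
    rule: str
    severity: str  # "error" | "warning"
    message: str

    def sort_key(self) -> tuple:
        return (self.graph.value if self.graph else "", self.rule, self.message)


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]

    def finish(self) -> "ValidationReport":
        self.violations.sort(key=Violation.sort_key)
        return self

    def render(self) -> str:
        if not self.violations:
            return "valid: no violations"
        lines = []
        for v in self.violations:
            where = v.graph.value if v.graph else "(document)"
            lines.append(f"[{v.severity}] {v.rule} @ {where}: {v.message}")
        return "\n".join(lines)


@dataclass
class ValidationContext:
    predicates: PredicateTable = field(default_factory=PredicateTable)
    ng_classes: NamedGraphClassCatalog = field(default_factory=default_ng_catalog)
    terms: TermCatalog = field(default_factory=default_term_catalog)

    @classmethod
    def from_store(cls, store: QuadStore) -> "ValidationContext":
        return cls(store.predicates, store.ng_classes, store.terms)


# ---------------------------------------------------------------------------
# Per-graph helpers


class _GraphIndex:
    def __init__(self, g: NamedGraph, p: PredicateTable):
        self.g = g
        self.p = p
        self.by_pred: dict[Iri, list[Statement]] = {}
        self.types: dict[Iri, list[Iri]] = {}
        for st in g.sorted_statements():
            self.by_pred.setdefault(st.p, []).append(st)
            if st.p == p.rdf_type and isinstance(st.o, Iri):
                self.types.setdefault(st.s, []).append(st.o)

    def stmts(self, pred: Iri) -> list[Statement]:
        return self.by_pred.get(pred, [])

    def typed(self, s: Iri) -> list[Iri]:
        return self.types.get(s, [])


def _v(out: list[Violation], g: NamedGraph, rule: str, sev: str, msg: str) -> None:
    out.append(Violation(g.iri, rule, sev, msg))


def _closed_check(out, g, idx, accounted: set[Statement], key: str) -> None:
    for st in g.statements:
        if st not in accounted:
            _v(out, g, f"{key}.unexpected-statement", "error",
               f"statement not allowed by the {key} scheme: ({st.s}, {st.p}, {st.o})")


def _check_prefix(out, g, ctx, class_iri: Iri, want: Optional[str], rule: str) -> None:
    if want is None:
        return
    term = ctx.terms.by_iri(class_iri)
    if term is None:
        _v(out, g, rule + ".unknown-term", "warning",
           f"class {class_iri} is not in the term catalog; cannot confirm the {want!r} family")
    elif term.prefix != want:
        _v(out, g, rule + ".wrong-family", "error",
           f"class {term.prefix}:{term.label} is not from the {want!r} family")


# ---------------------------------------------------------------------------
# Scheme checkers, one per SchemeSpec kind


def _check_parthood(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    labels = idx.stmts(p.rdfs_label)
    if len(labels) != 1 or not isinstance(labels[0].o, Literal):
        _v(out, g, "parthood.label", "error",
           f"a parthood graph must label exactly one part (found {len(labels)} labels)")
        return
    focus = labels[0].s
    accounted: set[Statement] = {labels[0]}
    ftypes = [st for st in idx.stmts(p.rdf_type) if st.s == focus]
    if len(ftypes) != 1:
        _v(out, g, "parthood.type", "error",
           f"the labeled part must have exactly one class affiliation (found {len(ftypes)})")
    accounted |= set(ftypes)
    edges = idx.stmts(p.has_part)
    if len(edges) > 1:
        _v(out, g, "parthood.single-edge", "error",
           "a parthood graph records at most one parthood edge "
           f"(found {len(edges)}; one descriptive statement per graph)")
    for e in edges:
        accounted.add(e)
        if e.o != focus:
            _v(out, g, "parthood.edge-target", "error",
               "the parthood edge must point at the labeled part")
        if e.s == focus:
            _v(out, g, "parthood.self-parthood", "error", "a part cannot be its own parent")
    _closed_check(out, g, idx, accounted, "parthood")


def _check_quality(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    hq = idx.stmts(p.has_quality)
    accounted: set[Statement] = set(hq)
    if len(hq) != 1 or not isinstance(hq[0].o, Iri):
        _v(out, g, "quality.single-quality", "error",
           f"a quality graph attaches exactly one quality to one bearer (found {len(hq)})")
        _closed_check(out, g, idx, accounted | set(idx.stmts(p.rdf_type)), "quality")
        return
    q = hq[0].o
    qtypes = [st for st in idx.stmts(p.rdf_type) if st.s == q]
    if len(qtypes) != 1:
        _v(out, g, "quality.quality-type", "error",
           f"the quality instance must have exactly one class affiliation (found {len(qtypes)})")
    else:
        _check_prefix(out, g, ctx, qtypes[0].o, scheme.param("quality_prefix"), "quality.family")
    accounted |= set(qtypes)
    _closed_check(out, g, idx, accounted, "quality")


def _check_measurement(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    hq = idx.stmts(p.has_quality)
    accounted: set[Statement] = set(hq)
    if len(hq) != 1 or not isinstance(hq[0].o, Iri):
        _v(out, g, "measurement.single-quality", "error",
           f"a measurement graph measures exactly one quality (found {len(hq)})")
        _closed_check(out, g, idx, g.statements, "measurement")
        return
    q = hq[0].o
    qtypes = [st for st in idx.stmts(p.rdf_type) if st.s == q]
    if len(qtypes) != 1:
        _v(out, g, "measurement.quality-type", "error",
           "the measured quality must have exactly one class affiliation")
    else:
        _check_prefix(out, g, ctx, qtypes[0].o, scheme.param("quality_prefix"), "measurement.family")
    accounted |= set(qtypes)
    values = [st for st in idx.stmts(p.has_value) if st.s == q]
    if len(values) != 1 or not isinstance(values[0].o, Literal) or values[0].o.datatype != XSD_FLOAT:
        _v(out, g, "measurement.value", "error",
           "the quality must carry exactly one float measurement value")
    accounted |= set(values)
    units = [st for st in idx.stmts(p.has_unit) if st.s == q]
    if len(units) != 1 or not isinstance(units[0].o, Iri):
        _v(out, g, "measurement.unit", "error",
           "the quality must reference exactly one unit instance")
        _closed_check(out, g, idx, accounted | set(idx.stmts(p.rdf_type)), "measurement")
        return
    accounted |= set(units)
    u = units[0].o
    utypes = [st for st in idx.stmts(p.rdf_type) if st.s == u]
    if len(utypes) != 1:
        _v(out, g, "measurement.unit-type", "error",
           "the unit instance must have exactly one class affiliation")
    else:
        _check_prefix(out, g, ctx, utypes[0].o, scheme.param("unit_prefix"), "measurement.unit-family")
    accounted |= set(utypes)
    _closed_check(out, g, idx, accounted, "measurement")


def _check_process_graph(out, g, idx, ctx, key: str,
                         min_in: int, max_in: Optional[int],
                         min_out: int, max_out: Optional[int],
                         inputs_typed: str, outputs_typed: str) -> None:
    """Shared shape for assay and collection graphs.

    ``inputs_typed``/``outputs_typed``: "required", "optional" or "forbidden" —
    whether the linked input/output resources must carry a type triple inside
    this graph (assay outputs are named-graph IRIs typed in the assertions
    graph, so typing them here is forbidden).
    """
    p = ctx.predicates
    link_subjects = sorted(
        {st.s for st in idx.stmts(p.has_specified_input)}
        | {st.s for st in idx.stmts(p.has_specified_output)}
    )
    if len(link_subjects) != 1:
        _v(out, g, f"{key}.single-process", "error",
           f"expected exactly one process instance, found {len(link_subjects)}")
        _closed_check(out, g, idx, g.statements, key)
        return
    proc = link_subjects[0]
    accounted: set[Statement] = set()
    ptypes = [st for st in idx.stmts(p.rdf_type) if st.s == proc]
    if len(ptypes) != 1:
        _v(out, g, f"{key}.process-type", "error",
           "the process must have exactly one class affiliation")
    accounted |= set(ptypes)

    linked: set[Iri] = set()
    for pred, lo, hi, typing_mode, role in (
        (p.has_specified_input, min_in, max_in, inputs_typed, "input"),
        (p.has_specified_output, min_out, max_out, outputs_typed, "output"),
    ):
        links = idx.stmts(pred)
        if len(links) < lo or (hi is not None and len(links) > hi):
            bound = f"at least {lo}" if hi is None else f"exactly {lo}" if lo == hi else f"{lo}..{hi}"
            _v(out, g, f"{key}.{role}-count", "error",
               f"the process must have {bound} specified {role}(s), found {len(links)}")
        for st in links:
            accounted.add(st)
            if not isinstance(st.o, Iri):
                _v(out, g, f"{key}.{role}-kind", "error", f"specified {role} must be a resource")
                continue
            linked.add(st.o)
            n_types = len(idx.typed(st.o))
            if typing_mode == "required" and n_types != 1:
                _v(out, g, f"{key}.{role}-type", "error",
                   f"specified {role} {st.o} must be typed exactly once in this graph")
            elif typing_mode == "forbidden" and n_types:
                _v(out, g, f"{key}.{role}-type", "error",
                   f"specified {role} {st.o} is a named-graph reference and must not be typed here")
            elif typing_mode == "optional" and n_types > 1:
                _v(out, g, f"{key}.{role}-type", "error",
                   f"specified {role} {st.o} carries {n_types} class affiliations")

    for pred, name in ((p.agent, "agent"), (p.device, "device"),
                       (p.protocol, "protocol"), (p.place, "place")):
        links = [st for st in idx.stmts(pred) if st.s == proc]
        if len(links) > 1:
            _v(out, g, f"{key}.{name}-count", "error", f"at most one {name} per process")
        for st in links:
            accounted.add(st)
            if not isinstance(st.o, Iri) or len(idx.typed(st.o)) != 1:
                _v(out, g, f"{key}.{name}-type", "error",
                   f"the {name} must be an instance typed exactly once in this graph")
            else:
                linked.add(st.o)
    dates = [st for st in idx.stmts(p.date) if st.s == proc]
    if len(dates) > 1:
        _v(out, g, f"{key}.date-count", "error", "at most one date per process")
    for st in dates:
        accounted.add(st)
        if not isinstance(st.o, Literal):
            _v(out, g, f"{key}.date-kind", "error", "the date must be a literal")

    # every node typed in this graph must be the process or linked to it
    for s, types in idx.types.items():
        if s == proc:
            continue
        for t in types:
            st = Statement(s, p.rdf_type, t)
            if s in linked:
                accounted.add(st)
            else:
                _v(out, g, f"{key}.orphan-instance", "error",
                   f"{s} is typed in this graph but not linked to the process")
                accounted.add(st)
    # labels allowed on linked, typed instances
    for st in idx.stmts(p.rdfs_label):
        if st.s in linked and idx.typed(st.s) and isinstance(st.o, Literal):
            accounted.add(st)
    _closed_check(out, g, idx, accounted, key)


def _check_assay(out, g, idx, ctx, scheme) -> None:
    _check_process_graph(out, g, idx, ctx, "assay",
                         min_in=1, max_in=None, min_out=1, max_out=None,
                         inputs_typed="optional", outputs_typed="forbidden")


def _check_collection(out, g, idx, ctx, scheme) -> None:
    _check_process_graph(out, g, idx, ctx, "collection",
                         min_in=1, max_in=1, min_out=1, max_out=1,
                         inputs_typed="required", outputs_typed="required")


def _check_history(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    in_links = idx.stmts(p.has_specified_input)
    out_links = idx.stmts(p.has_specified_output)
    processes = sorted({st.s for st in in_links} | {st.s for st in out_links})
    if not processes:
        _v(out, g, "history.no-steps", "error", "a specimen history needs at least one step")
        _closed_check(out, g, idx, set(), "history")
        return
    accounted: set[Statement] = set(in_links) | set(out_links)
    specimens: set[Iri] = set()
    dag = nx.DiGraph()
    for proc in processes:
        ptypes = [st for st in idx.stmts(p.rdf_type) if st.s == proc]
        if len(ptypes) != 1:
            _v(out, g, "history.process-type", "error",
               f"processing step {proc} must have exactly one class affiliation")
        accounted |= set(ptypes)
        ins = [st.o for st in in_links if st.s == proc and isinstance(st.o, Iri)]
        outs = [st.o for st in out_links if st.s == proc and isinstance(st.o, Iri)]
        if not ins or not outs:
            _v(out, g, "history.step-arity", "error",
               f"processing step {proc} needs at least one input and one output")
        specimens |= set(ins) | set(outs)
        for i in ins:
            for o in outs:
                dag.add_edge(i.value, o.value)
    if dag.edges and not nx.is_directed_acyclic_graph(dag):
        _v(out, g, "history.cycle", "error",
           "a specimen cannot be an input of a step that transitively produced it")
    for s in sorted(specimens):
        n = len(idx.typed(s))
        if n != 1:
            _v(out, g, "history.specimen-type", "error",
               f"specimen {s} must be typed exactly once in this graph (found {n})")
        accounted |= {st for st in idx.stmts(p.rdf_type) if st.s == s}
    for s, types in idx.types.items():
        if s in specimens or s in processes:
            continue
        for t in types:
            accounted.add(Statement(s, p.rdf_type, t))
        _v(out, g, "history.orphan-instance", "error",
           f"{s} is typed in this graph but is neither a step nor a specimen")
    for st in idx.stmts(p.rdfs_label):
        if st.s in specimens and isinstance(st.o, Literal):
            accounted.add(st)
    _closed_check(out, g, idx, accounted, "history")


def _section_class_iris(ctx) -> dict[Iri, str]:
    return {ctx.terms.get("iao", lab).iri: key for key, lab in SECTION_KEYS}


def _check_document(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    doc_cls = ctx.terms.get("iao", "document").iri
    docs = sorted({st.s for st in idx.stmts(p.rdf_type) if st.o == doc_cls})
    if len(docs) != 1:
        _v(out, g, "document.single-document", "error",
           f"a document graph must type exactly one document (found {len(docs)})")
        _closed_check(out, g, idx, g.statements, "document")
        return
    doc = docs[0]
    accounted: set[Statement] = {Statement(doc, p.rdf_type, doc_cls)}
    sec_classes = _section_class_iris(ctx)
    seen_keys: list[str] = []
    section_nodes: set[Iri] = set()
    for st in idx.stmts(p.has_part):
        if st.s != doc:
            _v(out, g, "document.foreign-part", "error",
               f"only the document may have parts in this graph (subject {st.s})")
            accounted.add(st)
            continue
        accounted.add(st)
        if not isinstance(st.o, Iri):
            _v(out, g, "document.part-kind", "error", "document parts must be resources")
            continue
        types = idx.typed(st.o)
        if len(types) != 1 or types[0] not in sec_classes:
            _v(out, g, "document.section-type", "error",
               f"document part {st.o} must be typed exactly once with an IAO section class")
        else:
            seen_keys.append(sec_classes[types[0]])
            section_nodes.add(st.o)
        for t in types:
            accounted.add(Statement(st.o, p.rdf_type, t))
    dup = {k for k in seen_keys if seen_keys.count(k) > 1}
    if dup:
        _v(out, g, "document.duplicate-section", "error",
           f"duplicate sections: {sorted(dup)}")
    for key in REQUIRED_SECTION_KEYS:
        if key not in seen_keys:
            _v(out, g, "document.required-section", "error",
               f"the {key!r} section is mandatory")
    # typed section nodes must be attached to the document
    for s, types in idx.types.items():
        for t in types:
            if t in sec_classes and s not in section_nodes:
                _v(out, g, "document.orphan-section", "error",
                   f"{s} is typed as a section but not a part of the document")
                accounted.add(Statement(s, p.rdf_type, t))
    texts = idx.stmts(p.has_text)
    per_sec: dict[Iri, int] = {}
    for st in texts:
        accounted.add(st)
        if st.s not in section_nodes or not isinstance(st.o, Literal):
            _v(out, g, "document.text-placement", "error",
               "free text may only be attached to a section, as a literal")
        per_sec[st.s] = per_sec.get(st.s, 0) + 1
    if any(n > 1 for n in per_sec.values()):
        _v(out, g, "document.text-count", "error", "at most one free text per section")
    # assertions registration
    a_cls = ctx.ng_classes.term("assertions").iri
    a_types = [st for st in idx.stmts(p.rdf_type) if st.o == a_cls]
    links = [st for st in idx.stmts(p.has_assertions_graph)]
    accounted |= set(a_types) | set(links)
    if len(a_types) != 1 or len(links) != 1 or links[0].s != doc \
            or not isinstance(links[0].o, Iri) or a_types[0].s != links[0].o:
        _v(out, g, "document.assertions-registration", "error",
           "the document graph must register exactly one assertions named graph "
           "(a type triple plus a link from the document)")
    _closed_check(out, g, idx, accounted, "document")


def _check_assertions(out, g, idx, ctx, scheme) -> None:
    p = ctx.predicates
    ia_cls = ctx.terms.get("ngo", "instance anatomy").iri
    anatomies = sorted({st.s for st in idx.stmts(p.rdf_type) if st.o == ia_cls})
    if len(anatomies) != 1:
        _v(out, g, "assertions.single-anatomy", "error",
           f"exactly one instance anatomy expected (found {len(anatomies)})")
        _closed_check(out, g, idx, g.statements, "assertions")
        return
    anatomy = anatomies[0]
    accounted: set[Statement] = {Statement(anatomy, p.rdf_type, ia_cls)}
    parts = idx.stmts(p.has_part)
    results_side = [st for st in parts if isinstance(st.o, Iri) and st.o == anatomy]
    if len(results_side) != 1:
        _v(out, g, "assertions.anatomy-attachment", "error",
           "the instance anatomy must be a part of exactly one (results section) resource")
    accounted |= set(results_side)
    results_subj = results_side[0].s if results_side else None

    desc_kinds = ctx.ng_classes.keys_of_kind("parthood", "quality", "measurement")
    meta_kinds = ctx.ng_classes.keys_of_kind("assay", "collection", "history")
    referenced: set[Iri] = set()
    n_meta = 0
    for st in parts:
        if st in accounted:
            continue
        accounted.add(st)
        if not isinstance(st.o, Iri):
            _v(out, g, "assertions.part-kind", "error", "graph references must be resources")
            continue
        types = idx.typed(st.o)
        if len(types) != 1:
            _v(out, g, "assertions.graph-type", "error",
               f"referenced graph {st.o} must be typed exactly once (found {len(types)})")
            for t in types:
                accounted.add(Statement(st.o, p.rdf_type, t))
            continue
        key = ctx.ng_classes.key_for_class(types[0])
        accounted.add(Statement(st.o, p.rdf_type, types[0]))
        referenced.add(st.o)
        if st.s == anatomy:
            if key not in desc_kinds:
                _v(out, g, "assertions.description-class", "error",
                   f"{st.o} is part of the instance anatomy but typed "
                   f"{types[0]} ({key}), not a description named-graph class")
        elif results_subj is not None and st.s == results_subj:
            _v(out, g, "assertions.results-extra-part", "error",
               "the results section may only have the instance anatomy as a part here")
        else:
            n_meta += 1
            if key not in meta_kinds:
                _v(out, g, "assertions.metadata-class", "error",
                   f"{st.o} is attached to the methods section but typed "
                   f"{types[0]} ({key}), not a metadata named-graph class")
    methods_subjects = sorted({st.s for st in parts if st not in set(results_side)
                               and st.s != anatomy})
    if len(methods_subjects) > 1:
        _v(out, g, "assertions.single-methods-section", "error",
           f"metadata graphs attach to one methods section, found subjects {methods_subjects}")
    if n_meta == 0:
        _v(out, g, "assertions.no-metadata", "warning",
           "no metadata graphs recorded for this description")
    # typed graph nodes must be referenced
    for s, types in idx.types.items():
        if s == anatomy or s in referenced:
            continue
        for t in types:
            accounted.add(Statement(s, p.rdf_type, t))
        _v(out, g, "assertions.orphan-graph", "error",
           f"{s} is typed here but not attached to the anatomy or the methods section")
    _closed_check(out, g, idx, accounted, "assertions")


def _check_unclassified(out, g, idx, ctx, scheme) -> None:
    _v(out, g, "unclassified.no-scheme", "warning",
       "graph has no recoverable named-graph class; its scheme cannot be checked")


_CHECKERS = {
    "parthood": _check_parthood,
    "quality": _check_quality,
    "measurement": _check_measurement,
    "assay": _check_assay,
    "collection": _check_collection,
    "history": _check_history,
    "document": _check_document,
    "assertions": _check_assertions,
    "unclassified": _check_unclassified,
}


def validate_named_graph(g: NamedGraph, ctx: Optional[ValidationContext] = None) -> ValidationReport:
    """Check one named graph against the data scheme of its class."""
    ctx = ctx or ValidationContext()
    key = ctx.ng_classes.key_for_class(g.ng_class.iri)
    if key is None:
        raise CatalogError(f"named-graph class not in catalog: {g.ng_class.iri}")
    scheme = ctx.ng_classes.scheme(key)
    out: list[Violation] = []
    _CHECKERS[scheme.kind](out, g, _GraphIndex(g, ctx.predicates), ctx, scheme)
    return ValidationReport(out).finish()


# ---------------------------------------------------------------------------
# Document-level validation


def _doc_error(out: list[Violation], rule: str, msg: str) -> None:
    out.append(Violation(None, rule, "error", msg))


def validate_document(store: QuadStore, doc: Iri) -> ValidationReport:
    """Whole-document referential integrity plus per-graph scheme checks."""
    ctx = ValidationContext.from_store(store)
    p = store.predicates
    out: list[Violation] = []

    try:
        doc_graph_iri = locate_document_graph(store, doc)
    except (NotFoundError, AmbiguityError) as exc:
        _doc_error(out, "doc.document-graph", str(exc))
        return ValidationReport(out).finish()
    graphs_to_check: list[Iri] = [doc_graph_iri]

    try:
        assertions_iri = locate_assertions_graph(store, doc_graph_iri)
    except (NotFoundError, AmbiguityError) as exc:
        _doc_error(out, "doc.assertions-graph", str(exc))
        assertions_iri = None
    if assertions_iri is not None and assertions_iri not in store:
        _doc_error(out, "doc.dangling-assertions",
                   f"assertions graph {assertions_iri} is registered but not in the store")
        assertions_iri = None

    anatomy = None
    desc_refs: list[Iri] = []
    meta_refs: list[Iri] = []
    if assertions_iri is not None:
        graphs_to_check.append(assertions_iri)
        try:
            anatomy = locate_instance_anatomy(store, assertions_iri)
        except (NotFoundError, AmbiguityError) as exc:
            _doc_error(out, "doc.instance-anatomy", str(exc))
        ag = store.get_graph(assertions_iri)
        declared_type: dict[Iri, Iri] = {}
        for st in ag.statements:
            if st.p == p.rdf_type and isinstance(st.o, Iri):
                declared_type[st.s] = st.o
        for st in sorted(ag.statements):
            if st.p != p.has_part or not isinstance(st.o, Iri):
                continue
            if anatomy is not None and st.o == anatomy:
                continue
            target = st.o
            if st.s == anatomy:
                desc_refs.append(target)
            else:
                meta_refs.append(target)
            if target not in store:
                _doc_error(out, "doc.dangling-graph",
                           f"referenced graph {target} does not resolve in the store")
                continue
            graphs_to_check.append(target)
            declared = declared_type.get(target)
            actual = store.get_graph(target).ng_class.iri
            if declared is not None and declared != actual:
                _doc_error(out, "doc.class-mismatch",
                           f"{target} declared as {declared} but stored as {actual}")

        # the assertions graph must hang off the document's own sections
        dg = store.get_graph(doc_graph_iri)
        sec_classes = _section_class_iris(ctx)
        sections: dict[str, Iri] = {}
        for st in dg.statements:
            if st.p == p.rdf_type and isinstance(st.o, Iri) and st.o in sec_classes:
                sections[sec_classes[st.o]] = st.s
        results_sec = sections.get("results")
        methods_sec = sections.get("methods")
        ag_part_subjects = {st.s for st in ag.statements if st.p == p.has_part}
        if results_sec is not None and anatomy is not None:
            if Statement(results_sec, p.has_part, anatomy) not in ag.statements:
                _doc_error(out, "doc.results-link",
                           "the instance anatomy is not a part of this document's results section")
        if methods_sec is not None and meta_refs:
            foreign = ag_part_subjects - {anatomy, results_sec, methods_sec} - {None}
            if foreign:
                _doc_error(out, "doc.methods-link",
                           f"metadata graphs attach to {sorted(i.value for i in foreign)}, "
                           "not this document's methods section")

    # partonomy checks over the resolvable parthood graphs
    parthood_cls = store.ng_classes.term("parthood").iri
    parthood_stmts: set[Statement] = set()
    for iri in desc_refs:
        if iri in store and store.get_graph(iri).ng_class.iri == parthood_cls:
            parthood_stmts |= store.get_graph(iri).statements
    bearers_known: set[Iri] = set()
    if parthood_stmts:
        edges = [(st.s, st.o) for st in parthood_stmts
                 if st.p == p.has_part and isinstance(st.o, Iri)]
        children = [c for _par, c in edges]
        multi = sorted({c.value for c in children if children.count(c) > 1})
        if multi:
            out.append(Violation(None, "doc.multiple-parents", "warning",
                                 f"parts with more than one parent: {multi}"))
        try:
            from .store import extract_partonomy

            partonomy = extract_partonomy(parthood_stmts, p)
            bearers_known = partonomy.nodes
        except CycleError as exc:
            _doc_error(out, "doc.partonomy-cycle", str(exc))
        except MalformedPartonomyError as exc:
            _doc_error(out, "doc.partonomy-root", str(exc))

    # assay provenance: outputs must be description graphs of this anatomy
    assay_cls = store.ng_classes.term("assay-data").iri
    covered: set[Iri] = set()
    for iri in meta_refs:
        if iri not in store or store.get_graph(iri).ng_class.iri != assay_cls:
            continue
        for st in store.get_graph(iri).statements:
            if st.p == p.has_specified_output and isinstance(st.o, Iri):
                covered.add(st.o)
                if st.o not in set(desc_refs):
                    out.append(Violation(iri, "doc.assay-output-unlisted", "error",
                                         f"assay output {st.o} is not among the "
                                         "anatomy's description graphs"))
    for iri in desc_refs:
        if iri not in covered:
            out.append(Violation(iri, "doc.no-provenance", "warning",
                                 "description graph is not the output of any recorded assay"))

    # quality/measurement bearers should be partonomy nodes
    quality_keys = store.ng_classes.keys_of_kind("quality", "measurement")
    quality_cls = {store.ng_classes.term(k).iri for k in quality_keys}
    for iri in desc_refs:
        if iri not in store:
            continue
        g = store.get_graph(iri)
        if g.ng_class.iri not in quality_cls:
            continue
        for st in g.statements:
            if st.p == p.has_quality and st.s not in bearers_known:
                out.append(Violation(iri, "doc.bearer-outside-partonomy", "warning",
                                     f"quality bearer {st.s} is not a node of the partonomy"))

    # per-graph scheme conformance
    for iri in sorted(set(graphs_to_check)):
        out.extend(validate_named_graph(store.get_graph(iri), ctx).violations)

    return ValidationReport(out).finish()


# ---------------------------------------------------------------------------
# Required statements (for mutation testing)


def required_statements(g: NamedGraph, ctx: Optional[ValidationContext] = None) -> set[Statement]:
    """The statements of ``g`` whose removal must make document validation
    fail.

    Optional statements — those the schemes deliberately tolerate losing — are
    section free texts, dates, labels on context instances and specimens,
    one-of-many assay input/output links (the model flags an assay-less
    description graph only as a warning), and type triples on extra assay
    inputs.
    """
    ctx = ctx or ValidationContext()
    p = ctx.predicates
    key = ctx.ng_classes.key_for_class(g.ng_class.iri)
    kind = ctx.ng_classes.scheme(key).kind if key else "unclassified"
    idx = _GraphIndex(g, p)
    optional: set[Statement] = set()
    if kind == "document":
        optional |= set(idx.stmts(p.has_text))
    elif kind in ("assay", "collection"):
        optional |= set(idx.stmts(p.date))
        optional |= set(idx.stmts(p.rdfs_label))
        if kind == "assay":
            ins = idx.stmts(p.has_specified_input)
            outs = idx.stmts(p.has_specified_output)
            if len(outs) > 1:
                optional |= set(outs)
            if len(ins) > 1:
                # an input link is only load-bearing if its object is typed
                # in-graph (deleting it would orphan the type triple)
                optional |= {st for st in ins
                             if isinstance(st.o, Iri) and not idx.typed(st.o)}
            # typing an extra substance input is allowed but not mandated
            for st in ins:
                if isinstance(st.o, Iri):
                    for t in idx.typed(st.o):
                        optional.add(Statement(st.o, p.rdf_type, t))
    elif kind == "history":
        optional |= set(idx.stmts(p.rdfs_label))
        links = idx.stmts(p.has_specified_input) + idx.stmts(p.has_specified_output)
        refs: dict[Iri, int] = {}
        for st in links:
            if isinstance(st.o, Iri):
                refs[st.o] = refs.get(st.o, 0) + 1
        for direction in (p.has_specified_input, p.has_specified_output):
            by_proc: dict[Iri, list[Statement]] = {}
            for st in idx.stmts(direction):
                by_proc.setdefault(st.s, []).append(st)
            for sts in by_proc.values():
                if len(sts) > 1:
                    optional |= {st for st in sts
                                 if isinstance(st.o, Iri) and refs.get(st.o, 0) > 1}
    elif kind == "unclassified":
        return set()
    return set(g.statements) - optional
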