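"""Reading and writing stores and query results.

TriG is the canonical human-facing format (its named-graph blocks mirror the
structure of a description document); N-Quads is the line-oriented exchange
format. Both go through rdflib. CSV and JSON exports render statement sets
and whole documents for downstream tools.
"""

from __future__ import annotations

import csv
import io as _io
import json
from typing import Iterable, Optional

import rdflib
from rdflib import BNode, URIRef
from rdflib import Literal as RLiteral

from .core import (
    Iri,
    Literal,
    NamedGraph,
    Quad,
    RDF_LANG_STRING,
    Statement,
    TermRef,
    XSD_STRING,
)
from .errors import NotFoundError, ParseError
from .store import (
    QuadStore,
    locate_assertions_graph,
    locate_document_graph,
    locate_instance_anatomy,
)

__all__ = [
    "write_quads",
    "read_quads",
    "export_csv",
    "export_document_json",
]


def _to_rdflib_node(o):
    if isinstance(o, Iri):
        return URIRef(o.value)
    if o.lang is not None:
        return RLiteral(o.lexical, lang=o.lang)
    if o.datatype == XSD_STRING:
        return RLiteral(o.lexical)
    return RLiteral(o.lexical, datatype=URIRef(o.datatype.value))


def _from_rdflib_node(node):
    if isinstance(node, URIRef):
        return Iri(str(node))
    if isinstance(node, BNode):
        raise ParseError("blank nodes are not admitted by the data model")
    if node.language is not None:
        return Literal(str(node), RDF_LANG_STRING, node.language)
    dt = Iri(str(node.datatype)) if node.datatype is not None else XSD_STRING
    return Literal(str(node), dt)


def write_quads(store: QuadStore, format: str = "trig") -> str:
    """Serialize every quad of the store; graph IRIs are preserved."""
    if format not in ("trig", "nquads"):
        raise ParseError(f"unsupported quad format: {format!r}")
    ds = rdflib.Dataset()
    for g in store.graphs():
        ctx = ds.graph(URIRef(g.iri.value))
        for st in g.sorted_statements():
            ctx.add((URIRef(st.s.value), URIRef(st.p.value), _to_rdflib_node(st.o)))
    return ds.serialize(format=format)


def _recover_ng_class(graph_iri: Iri, statements, type_index, store: QuadStore) -> TermRef:
    """Recover a graph's named-graph class from type triples elsewhere in the
    store (assertions/document graphs type every graph they reference). The
    document graph itself is recognized by the iao:document typing it
    contains; anything else falls back to 'unclassified'."""
    declared = type_index.get(graph_iri)
    if declared is not None:
        key = store.ng_classes.key_for_class(declared)
        if key is not None:
            return store.ng_classes.term(key)
    p = store.predicates
    doc_cls = store.terms.get("iao", "document").iri
    if any(st.p == p.rdf_type and st.o == doc_cls for st in statements):
        return store.ng_classes.term("document")
    return store.ng_classes.term("unclassified")


def read_quads(
    text: str,
    format: str = "trig",
    store: Optional[QuadStore] = None,
) -> QuadStore:
    """Parse serialized quads into a store, recovering each graph's
    named-graph class from the type triples of the document/assertions
    graphs. Graphs without a recoverable class are typed 'unclassified' (the
    validator then warns)."""
    if format not in ("trig", "nquads"):
        raise ParseError(f"unsupported quad format: {format!r}")
    store = store or QuadStore()
    ds = rdflib.Dataset()
    try:
        ds.parse(data=text, format=format)
    except Exception as exc:  # rdflib raises several parser-specific types
        raise ParseError(f"could not parse {format} input: {exc}") from exc

    raw: dict[Iri, set[Statement]] = {}
    for s, p, o, g in ds.quads((None, None, None, None)):
        if g is None or str(g) == "urn:x-rdflib:default":
            continue
        if isinstance(s, BNode) or isinstance(g, BNode):
            raise ParseError("blank nodes are not admitted by the data model")
        st = Statement(Iri(str(s)), Iri(str(p)), _from_rdflib_node(o))
        raw.setdefault(Iri(str(g)), set()).add(st)

    rdf_type = store.predicates.rdf_type
    type_index: dict[Iri, Iri] = {}
    for stmts in raw.values():
        for st in stmts:
            if st.p == rdf_type and isinstance(st.o, Iri) and st.s in raw:
                type_index[st.s] = st.o
    for graph_iri in sorted(raw):
        stmts = raw[graph_iri]
        ng_class = _recover_ng_class(graph_iri, stmts, type_index, store)
        store.add_graph(NamedGraph(graph_iri, ng_class, frozenset(stmts)))
    return store


# ---------------------------------------------------------------------------
# Tabular / JSON exports

CSV_HEADER = ("subject", "predicate", "object", "object_datatype")


def export_csv(statements: Iterable[Statement]) -> str:
    """One RFC-4180 row per statement, sorted; the datatype column is empty
    for resource objects."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\r\n")
    w.writerow(CSV_HEADER)
    for st in sorted(statements):
        if isinstance(st.o, Iri):
            w.writerow((st.s.value, st.p.value, st.o.value, ""))
        else:
            dt = st.o.datatype.value if st.o.lang is None else f"@{st.o.lang}"
            w.writerow((st.s.value, st.p.value, st.o.lexical, dt))
    return buf.getvalue()


def _statement_obj(st: Statement) -> dict:
    if isinstance(st.o, Iri):
        o: dict = {"kind": "iri", "value": st.o.value}
    else:
        o = {"kind": "literal", "value": st.o.lexical, "datatype": st.o.datatype.value}
        if st.o.lang:
            o["lang"] = st.o.lang
    return {"subject": st.s.value, "predicate": st.p.value, "object": o}


def _graph_obj(store: QuadStore, iri: Iri) -> dict:
    g = store.get_graph(iri)
    key = store.ng_classes.key_for_class(g.ng_class.iri) or "unclassified"
    return {
        "iri": g.iri.value,
        "class_key": key,
        "class_iri": g.ng_class.iri.value,
        "class_label": g.ng_class.label,
        "statements": [_statement_obj(st) for st in g.sorted_statements()],
    }


def export_document_json(store: QuadStore, doc: Iri, tolerate_errors: bool = False) -> str:
    """Nested JSON rendering of one description document: document →
    sections → instance anatomy → named-graph objects. Key order is stable,
    so re-export after a round-trip is byte-identical."""
    from .validation import validate_document

    report = validate_document(store, doc)
    if not report.passed and not tolerate_errors:
        raise NotFoundError(
            "document does not validate; pass tolerate_errors=True to export anyway:\n"
            + report.render()
        )
    p = store.predicates
    doc_graph = locate_document_graph(store, doc)
    assertions = locate_assertions_graph(store, doc_graph)
    anatomy = locate_instance_anatomy(store, assertions)
    dg = store.get_graph(doc_graph)
    ag = store.get_graph(assertions)

    sections = []
    sec_nodes = sorted(
        st.o for st in dg.statements
        if st.s == doc and st.p == p.has_part and isinstance(st.o, Iri)
    )
    texts = {st.s: st.o.lexical for st in dg.statements
             if st.p == p.has_text and isinstance(st.o, Literal)}
    types = {st.s: st.o for st in dg.statements
             if st.p == p.rdf_type and isinstance(st.o, Iri)}
    for sec in sec_nodes:
        entry = {"iri": sec.value, "class_iri": types[sec].value if sec in types else None}
        if sec in texts:
            entry["text"] = texts[sec]
        sections.append(entry)

    desc_iris = sorted(
        st.o for st in ag.statements
        if st.s == anatomy and st.p == p.has_part and isinstance(st.o, Iri) and st.o in store
    )
    meta_iris = sorted(
        st.o for st in ag.statements
        if st.p == p.has_part and isinstance(st.o, Iri)
        and st.s != anatomy and st.o != anatomy and st.o in store
    )
    payload = {
        "document": doc.value,
        "document_graph": _graph_obj(store, doc_graph),
        "sections": sections,
        "assertions_graph": _graph_obj(store, assertions),
        "instance_anatomy": anatomy.value,
        "description_graphs": [_graph_obj(store, i) for i in desc_iris],
        "metadata_graphs": [_graph_obj(store, i) for i in meta_iris],
        "valid": report.passed,
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
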