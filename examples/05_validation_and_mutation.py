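"""Scheme validation as a data standard.

Every named-graph class has exactly one data scheme. Deleting a required
statement from any graph (here: the float value of the head-volume
measurement) must flip document validation to failing — this is what makes
descriptions from different authors comparable."""

from anatomykg import QuadStore, paper_example, validate_document
from anatomykg.core import NamedGraph

store, doc = paper_example()
print("intact document :", "PASS" if validate_document(store, doc).passed else "FAIL")

volume_cls = store.ng_classes.term("anatomical-structure-volume").iri
(volume_graph,) = [g for g in store.graphs() if g.ng_class.iri == volume_cls]
(value_stmt,) = [st for st in volume_graph.statements
                 if st.p == store.predicates.has_value]

mutated = QuadStore(store.predicates, store.ng_classes, store.terms)
for g in store.graphs():
    stmts = g.statements - {value_stmt} if g.iri == volume_graph.iri else g.statements
    mutated.add_graph(NamedGraph(g.iri, g.ng_class, frozenset(stmts)))

report = validate_document(mutated, doc)
print("value deleted   :", "PASS" if report.passed else "FAIL")
for v in report.errors:
    print(f"  [{v.severity}] {v.rule}: {v.message}")
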