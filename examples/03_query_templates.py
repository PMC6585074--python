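"""The standard query templates, step by step.

Starting from nothing but the document individual's IRI: find the document
named graph (it contains the document's type triple), find the assertions
graph registered inside it, find the instance anatomy inside that, then
union the parthood graphs and export the partonomy as CSV rows."""

from anatomykg import (
    export_csv,
    locate_assertions_graph,
    locate_document_graph,
    locate_instance_anatomy,
    paper_example,
    parthood_union,
)

store, doc = paper_example()
print(f"document individual : {doc}")

dg = locate_document_graph(store, doc)
print(f"document graph      : {dg}")
ag = locate_assertions_graph(store, dg)
print(f"assertions graph    : {ag}")
anatomy = locate_instance_anatomy(store, ag)
print(f"instance anatomy    : {anatomy}")

stmts = parthood_union(store, anatomy, ag)
print(f"\nparthood union has {len(stmts)} statements "
      "(2 for the root, 3 per further part):")
print(export_csv(stmts))
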