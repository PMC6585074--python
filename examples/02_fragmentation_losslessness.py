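"""Fragmentation loses no information.

Generates a random description, stores it as many single-statement named
graphs, re-unites them with the description-union query template, and
compares the result with the same description enumerated as one flat
statement set. Because every part and quality has its own IRI (no blank
nodes), the union reconnects exactly."""

from anatomykg import (
    description_union,
    locate_assertions_graph,
    locate_document_graph,
    locate_instance_anatomy,
)
from anatomykg.fixtures import FixtureConfig, generate_description, monolithic_description

cfg = FixtureConfig(seed=11, n_parts=9, p_texture=0.5, p_measurement=0.5)
store, doc, truth = generate_description(cfg)

dg = locate_document_graph(store, doc)
ag = locate_assertions_graph(store, dg)
anatomy = locate_instance_anatomy(store, ag)

fragmented = description_union(store, anatomy, ag)
monolithic = monolithic_description(truth)

print(f"description graphs in store : {len(truth.description_graphs)}")
print(f"statements after union      : {len(fragmented)}")
print(f"statements built monolithic : {len(monolithic)}")
print(f"set equality (lossless)     : {fragmented == monolithic}")
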