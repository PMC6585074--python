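# anatomykg

Instance-based anatomy knowledge graphs in typed RDF named graphs — a data
model and toolkit for recording morphological descriptions of individual
specimens as computer-parsable semantic graphs.

## The problem

Almost all morphological data are published as free text: hard to query,
hard to integrate with genomic or ecological data, and opaque to non-experts.
`anatomykg` records a description as an **ABox semantic graph**: every
described part, quality and process is an ontology *individual* with its own
IRI, instantiating a class from an existing ontology (HAO for hymenopteran
anatomy, PATO for qualities, UO for units, OBI for assays and specimen
processes, IAO for document structure, BFO for `has part`).

Because nothing is a blank node, the description can be **fragmented** into
many small named graphs — one descriptive statement per graph — and any
subset re-unites by plain set union without losing information:

* a *parthood graph* holds one part's class, label and (except for the
  partonomy root) the single `bfo:has part` edge from its direct parent:
  `(parent, has part, child)`, `(child, rdf:type, C)`, `(child, rdfs:label, …)`;
* a *quality graph* attaches one PATO quality instance to its bearer:
  `(bearer, has quality, q)`, `(q, rdf:type, Q)`;
* a *measurement graph* adds a float value and a typed unit individual —
  the five-statement shape `(bearer, has quality, q)`, `(q, rdf:type, Q)`,
  `(q, has value, "0.25"^^xsd:float)`, `(q, has unit, u)`,
  `(u, rdf:type, uo:milliliter)`.

Each named graph is itself a resource, typed by a **named-graph ontology
class** (`parthood named graph`, `assay data named graph`, …) with exactly
one associated data scheme; turning triples into **quads** this way is what
lets metadata point at individual description fragments. An *assay data
graph* records an observation process (specimen in, description graphs out,
plus who/where/when/device/protocol); *collection* and *history* graphs
record where the specimens came from, including forking processing chains.
An *assertions graph* ties the layers together: the document's results
section has an `instance anatomy` individual as a part, which has every
description graph as a part; the methods section has every metadata graph as
a part. The union over the instance anatomy's parts **is** the Anatomy
Knowledge Graph of the document.

On top of this sit the query templates (locate document graph → assertions
graph → instance anatomy → unions), **data views** (named selections of
named-graph classes, optionally unit-filtered), per-class **scheme
validation** plus whole-document referential integrity, TriG/N-Quads/CSV/JSON
serialization, a deterministic synthetic-description generator, and a small
CLI (`anatomy-kg generate | build | validate | query | export`).

## Worked example

```sh
python examples/01_worked_example.py
```

prints, for the bundled single-specimen example (a hymenopteran with a
0.25 ml head volume and a rugose thorax texture):

```
named graphs in the document:
  anatomical structure volume named graph         5 statements
  anatomical surface texture named graph          2 statements
  assay data named graph                         14 statements
  assertions named graph                         18 statements
  document named graph                           20 statements
  parthood named graph                            2 statements
  parthood named graph                            3 statements
  parthood named graph                            3 statements
  specimen collection named graph                 9 statements
  specimen history named graph                   15 statements

partonomy (root + direct parts):
  root: specimen A, whole organism
  specimen A, whole organism --has part--> head of specimen A
  specimen A, whole organism --has part--> thorax of specimen A

validation: passed=True, 0 errors, 0 warnings
```

One named graph per kind of statement: the root parthood graph has exactly
2 statements (type + label), each child graph 3 (type + label + parthood
edge), the texture graph 2, the volume measurement 5; assay, collection and
history graphs carry the metadata; the assertions graph (18 statements) wires
everything to the document's sections. The other example scripts demonstrate
losslessness of fragmentation (`02`), the query templates with CSV export
(`03`), data views and the metre-based unit filter (`04`), and validation
with a mutated measurement (`05`).

The same store is reachable from the shell:

```sh
anatomy-kg generate --seed 1 --out doc.trig
anatomy-kg validate doc.trig            # exit code 0/1
anatomy-kg query doc.trig --view parthood-view --format csv
anatomy-kg export doc.trig --format json
```

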