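# Methods

## The data model

A morphological description document is a set of **named graphs** in one
quad store. Every resource is an ontology individual with its own absolute
IRI; the model admits no blank nodes anywhere. That single constraint is
what makes the central property hold: a description fragmented into
one-statement-per-graph named graphs re-unites by set union into exactly the
graph one would have built monolithically, because fragments reconnect
through shared IRIs.

Three layers:

1. **Document layer.** An `iao:document` individual with one typed section
   individual per publication section (abstract … references), attached via
   `bfo:has part`. The methods and results sections are mandatory because
   they anchor the other two layers. The document graph also registers the
   assertions graph (its type triple plus a `has_assertions_graph` link), so
   the lookup chain document → assertions graph needs only this graph.
2. **Description layer.** Parthood graphs (root form: type + label; child
   form: type + label + one `has part` edge), quality graphs (2 statements)
   and measurement graphs (5 statements). A part's type and label are
   asserted only in its parthood graph; quality/measurement graphs refer to
   the bearer by IRI without re-typing it, keeping every graph minimal.
3. **Metadata layer.** Assay graphs (observation process: one specimen as
   specified input, ≥1 description graphs as specified output, optional
   agent/device/protocol/place/date), one collection graph (material entity
   in, specimen out), and a history graph holding the DAG of specimens
   derived by material-processing steps, forks allowed.

The **assertions graph** ties the layers: `(results section, has part,
instance anatomy)`, `(instance anatomy, has part, g)` for every description
graph `g`, `(methods section, has part, m)` for every metadata graph `m`,
with each referenced graph IRI typed by its named-graph class. The union
query templates filter on exactly these type triples.

### Vocabulary and predicates

The named-graph classes themselves are published by no ontology, so they are
minted once in a fixed local namespace (`…/anatomy-kg/ngo/`) recorded in the
bundled term catalog — stable and citable across documents, unlike a
per-document base. The parthood predicate is fixed to BFO `has part`
(BFO_0000051); all other predicates (`has quality` RO_0000086, `has value`
IAO_0000004, `has unit` IAO_0000039, OBI's specified input/output, local
defaults for agent/device/protocol/place and dcterms:date) live in a
configurable `PredicateTable`, because the model prescribes classes, not
predicate IRIs. The offline term catalog (TSV: prefix, IRI, label, source)
covers every class the model's figures need from IAO, OBI, BFO, PATO, UO,
HAO and NCBITaxon; a few numeric suffixes of minor section/anatomy classes
are illustrative rather than authoritative — the catalog is plain data and
user-editable, and "microscopy assay" is recorded under the `obi` prefix
with its source ontology re-pointable. An `anatomical-structure-length`
class ships alongside the volume class so that unit-filtered views have a
second measurement category to act on.

### IRI minting

`{base}{kind}/{counter:05d}-{uuid5(seed, kind, counter)[:10]}`. The counter
makes minting injective within a run by construction; the seeded UUID5 tag
makes output reproducible across runs and distinct across seeds. Same seed →
byte-identical TriG.

## Validation

Each named-graph class carries exactly one declarative `SchemeSpec`
(a shape-family kind plus parameters such as the accepted quality family), so
registering a new class — a colour quality category, say — needs no new
code. Shapes are **closed**: a statement the scheme cannot account for is an
error. Cardinalities: parthood = exactly one type + one label + at most one
incoming edge; measurement = the exact five-statement shape with a finite
`xsd:float`; process graphs require the process, its typed context
instances, and link/type pairing (a typed node not linked to the process is
an orphan error, a context link to an untyped node is an error).

Document-level validation adds referential integrity: every referenced graph
resolves and its declared class matches the stored one; every assay output
is among the anatomy's description graphs; the partonomy has one root and no
cycles; the assertions graph hangs off this document's own sections.
Severities are the package's own split: structural breakage is an error;
parts with several parents, description graphs with no recorded assay, and
quality bearers outside the partonomy are warnings — descriptions built from
several specimens legitimately leave provenance partial.

`required_statements` enumerates, per graph, the statements whose deletion
must flip document validation. The deliberately optional remainder: section
free texts, date literals, labels on specimens and process-context
instances, one-of-many assay output links (losing provenance for one
fragment is a warning), and type triples on extra assay inputs. On the
worked example this partitions the 91 statements into 76 required (all
killed) and 15 optional (all tolerated).

## Queries and views

The locate/union operations implement the standard SPARQL templates as
first-class functions with identical pattern semantics — testable without a
SPARQL endpoint, and each is checked against a brute-force scan over all
quads. Results are returned in lexicographic IRI order; unions drop graph
provenance by design (use `find_graphs_containing` when provenance is
needed). Data views name a set of named-graph class keys plus an optional
unit predicate; the metre-based filter ships with
meter/centimeter/millimeter/micrometer and is configuration, not a closed
list. View resolution is additive over disjoint class sets and monotone in
the class set.

## Serialization

TriG and N-Quads via rdflib; round-trips are identity on quad sets. A graph's
named-graph class is recovered on read from the type triples in the
assertions/document graphs; the document graph itself is recognized by the
`iao:document` typing it contains; anything else is typed `unclassified` and
draws a validator warning. CSV export is one RFC-4180 row per statement,
sorted. The JSON document rendering nests document → sections → instance
anatomy → graph objects with sorted keys, so re-export after a round-trip is
byte-identical.

## Synthetic descriptions

The generator emulates a realistic description document: a random partonomy
(uniform attachment, depth-capped), per-part texture and measurement
probabilities of 0.3 each, a 50/50 volume/length unit mix with log-uniform
values (0.001–10 ml; 0.1–100 length units — log-uniform because anatomical
magnitudes span orders of magnitude), two derived specimens by default with
fork probability 0.25, one collection record, and one assay per leaf
specimen partitioning the description graphs among them so provenance is
complete. Ground truth (the generating tree, every sampled value and IRI,
the per-assay graph assignment) is returned alongside for exact-recovery
tests, and `monolithic_description` rebuilds the flat statement set straight
from ground truth, independent of the builders — the reference for the
losslessness check.

What the generator does **not** emulate: free-text richness of real
descriptions, ontology-term misuse, multi-document stores with shared
specimens, and contradictory observations. Passing tests therefore show the
data model's structural guarantees, not robustness to messy real-world
curation.

Problem sizes used by the test suite and the acceptance script — 100 random
configurations for losslessness, up to 1,000 parts for partonomy recovery,
exhaustive single-statement mutation over the worked example — were chosen
as the smallest sizes at which the properties are non-trivial; all of them
run in seconds.

## Known limitations

* No OWL reasoning or entailment; class hierarchies (e.g. "is this PATO
  class a texture?") are approximated by catalog prefix membership.
* One description document per store is assumed by the CLI convenience
  commands; the library itself handles multi-document stores (views resolve
  per document).
* The worked example's partonomy places head and thorax directly under the
  organism and attaches the texture to the thorax; finer surface modeling
  (a distinct surface individual) would add one partonomy level.
* HTML rendering with tooltip definitions is out of scope; the JSON export
  carries labels and class IRIs so a renderer could be layered on.
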