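"""Deterministic synthetic description documents.

:func:`generate_description` produces a complete, validating description
document — random partonomy, sampled qualities and measurements, a specimen
collection record, a possibly forking specimen history, and assays that
partition the description graphs among the derived specimens — together with
a ground-truth record for recovery tests. Identical seeds give identical
stores, down to the serialized bytes.

:func:`paper_example` is the fixed worked example: a hymenopteran specimen
with a head volume measured in milliliter, a rugose thorax texture, a
microscopy assay, a live-trap collection record and a forked specimen
history — one named graph per figure of the data model.

:func:`monolithic_description` rebuilds the same description as one flat
statement set straight from the ground truth, bypassing the builders; it is
the independent reference for the losslessness property (fragmenting into
named graphs and re-uniting loses nothing).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from random import Random
from typing import Optional

from .builders import (
    AssayRecord,
    BuilderContext,
    CollectionRecord,
    DocumentMetadata,
    MeasurementRecord,
    ProcessingStep,
    QualityRecord,
    build_assay_graph,
    build_assertions_graph,
    build_collection_graph,
    build_document_graph,
    build_history_graph,
    build_measurement_graph,
    build_parthood_graph,
    build_quality_graph,
    build_root_parthood_graph,
)
from .core import (
    Instance,
    Iri,
    IriMinter,
    Literal,
    NamedGraph,
    PredicateTable,
    Statement,
    TermRef,
)
from .errors import ConfigurationError
from .store import QuadStore

__all__ = [
    "FixtureConfig",
    "GroundTruth",
    "PartTruth",
    "generate_description",
    "paper_example",
    "monolithic_description",
]

DEFAULT_BASE = "https://example.org/descriptions/"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generator. Probabilities are per part (qualities,
    measurements) or per processing step (forks)."""

    seed: int = 0
    n_parts: int = 8
    max_depth: int = 4
    p_texture: float = 0.3
    p_measurement: float = 0.3
    n_specimens: int = 2
    p_fork: float = 0.25
    p_volume: float = 0.5  # measurement unit mix: volume vs length
    base: str = DEFAULT_BASE

    def validate(self) -> None:
        if self.n_parts < 1:
            raise ConfigurationError("n_parts must be at least 1")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be at least 1")
        if self.n_specimens < 1:
            raise ConfigurationError("n_specimens must be at least 1")
        for name in ("p_texture", "p_measurement", "p_fork", "p_volume"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PartTruth:
    iri: Iri
    class_ref: TermRef
    label: str
    parent: Optional[Iri]


@dataclass(frozen=True)
class QualityTruth:
    bearer: Iri
    quality: Iri
    quality_class: TermRef
    category: str
    graph: Iri


@dataclass(frozen=True)
class MeasurementTruth:
    bearer: Iri
    quality: Iri
    quality_class: TermRef
    value: float
    unit_instance: Iri
    unit_class: TermRef
    category: str
    graph: Iri


@dataclass
class GroundTruth:
    """Everything the generator decided, for exact-recovery tests."""

    document: Iri
    anatomy: Iri
    assertions_graph: Iri
    results_section: Iri
    methods_section: Iri
    root: Iri
    parts: dict[Iri, PartTruth] = field(default_factory=dict)
    parthood_graph_of: dict[Iri, Iri] = field(default_factory=dict)
    qualities: list[QualityTruth] = field(default_factory=list)
    measurements: list[MeasurementTruth] = field(default_factory=list)
    assay_of_graph: dict[Iri, Iri] = field(default_factory=dict)
    specimen_edges: set[tuple[Iri, Iri]] = field(default_factory=set)
    description_graphs: list[Iri] = field(default_factory=list)
    metadata_graphs: list[Iri] = field(default_factory=list)

    def parent_map(self) -> dict[Iri, Iri]:
        return {
            t.iri: t.parent for t in self.parts.values() if t.parent is not None
        }


def _loguniform(rng: Random, lo: float, hi: float) -> float:
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def _q_of(graph: NamedGraph, p: PredicateTable) -> Iri:
    (q,) = [st.o for st in graph.statements if st.p == p.has_quality]
    assert isinstance(q, Iri)
    return q


def _unit_of(graph: NamedGraph, p: PredicateTable) -> Iri:
    (u,) = [st.o for st in graph.statements if st.p == p.has_unit]
    assert isinstance(u, Iri)
    return u


def _specimen_label(i: int) -> str:
    if i < 26:
        return f"specimen {string.ascii_uppercase[i]}"
    return f"specimen #{i}"


def generate_description(cfg: FixtureConfig) -> tuple[QuadStore, Iri, GroundTruth]:
    """Generate one complete description document. Deterministic per seed."""
    cfg.validate()
    store = QuadStore()
    ctx = BuilderContext(IriMinter(cfg.base, cfg.seed))
    ctx.terms = store.terms
    ctx.ng_classes = store.ng_classes
    ctx.predicates = store.predicates
    rng = Random(cfg.seed)
    p = ctx.predicates
    terms = ctx.terms

    anatomy_classes = terms.terms_with_prefix("hao")
    texture_classes = [terms.get("pato", "rugose"), terms.get("pato", "smooth")]

    # --- partonomy -------------------------------------------------------
    root_cls = terms.get("hao", "adult")
    root = ctx.new_instance(root_cls, f"described organism (seed {cfg.seed})")
    depth = {root.iri: 1}
    parts: dict[Iri, PartTruth] = {root.iri: PartTruth(root.iri, root_cls, root.label, None)}
    instances: dict[Iri, Instance] = {root.iri: root}
    order: list[Iri] = [root.iri]
    for i in range(1, cfg.n_parts):
        eligible = [iri for iri in order if depth[iri] < cfg.max_depth]
        parent_iri = rng.choice(eligible) if eligible else root.iri
        cls = rng.choice(anatomy_classes)
        child = ctx.new_instance(cls, f"{cls.label} {i}")
        depth[child.iri] = depth[parent_iri] + 1
        parts[child.iri] = PartTruth(child.iri, cls, child.label, parent_iri)
        instances[child.iri] = child
        order.append(child.iri)

    parthood_graphs: list[NamedGraph] = [build_root_parthood_graph(root, ctx)]
    parthood_graph_of = {root.iri: parthood_graphs[0].iri}
    for iri in order[1:]:
        t = parts[iri]
        g = build_parthood_graph(instances[t.parent], instances[iri], ctx)
        parthood_graphs.append(g)
        parthood_graph_of[iri] = g.iri

    # --- qualities and measurements --------------------------------------
    quality_graphs: list[NamedGraph] = []
    qualities: list[QualityTruth] = []
    measurement_graphs: list[NamedGraph] = []
    measurements: list[MeasurementTruth] = []
    for iri in order:
        if rng.random() < cfg.p_texture:
            qc = rng.choice(texture_classes)
            g = build_quality_graph(
                QualityRecord(instances[iri], qc, "anatomical-surface-texture"), ctx
            )
            quality_graphs.append(g)
            qualities.append(
                QualityTruth(iri, _q_of(g, p), qc, "anatomical-surface-texture", g.iri)
            )
        if rng.random() < cfg.p_measurement:
            if rng.random() < cfg.p_volume:
                qc = terms.get("pato", "volume")
                unit = terms.get("uo", "milliliter")
                category = "anatomical-structure-volume"
                value = _loguniform(rng, 1e-3, 10.0)
            else:
                qc = terms.get("pato", "length")
                unit = rng.choice(
                    [terms.get("uo", u) for u in ("millimeter", "centimeter", "meter")]
                )
                category = "anatomical-structure-length"
                value = _loguniform(rng, 0.1, 100.0)
            g = build_measurement_graph(
                MeasurementRecord(instances[iri], qc, value, unit, category), ctx
            )
            measurement_graphs.append(g)
            measurements.append(
                MeasurementTruth(
                    iri, _q_of(g, p), qc, value, _unit_of(g, p), unit, category, g.iri
                )
            )

    # --- specimens: collection + history ----------------------------------
    specimen_cls = terms.get("obi", "specimen")
    s0 = ctx.new_instance(specimen_cls, _specimen_label(0))
    collection = build_collection_graph(
        CollectionRecord(
            process=ctx.new_instance(terms.get("obi", "specimen collection process")),
            input_material=ctx.new_instance(
                terms.get("bfo", "material entity"), "field-collected organism"
            ),
            output_specimen=s0,
            device=ctx.new_instance(terms.get("obi", "device"), "live trap"),
            date="2018-05-04",
        ),
        ctx,
    )

    steps: list[ProcessingStep] = []
    leaves: list[Instance] = [s0]
    n_spec = 1
    processing_cls = terms.get("obi", "material processing")
    attempts = 0
    while len(leaves) < cfg.n_specimens or not steps:
        attempts += 1
        fork = rng.random() < cfg.p_fork or attempts > 4 * cfg.n_specimens
        if len(leaves) >= cfg.n_specimens:
            fork = False  # final guaranteed step on a single-specimen history
        leaf = leaves[rng.randrange(len(leaves))]
        proc = ctx.new_instance(processing_cls)
        n_out = 2 if fork else 1
        outs = tuple(
            ctx.new_instance(specimen_cls, _specimen_label(n_spec + j))
            for j in range(n_out)
        )
        n_spec += n_out
        steps.append(ProcessingStep(proc, (leaf,), outs))
        leaves.remove(leaf)
        leaves.extend(outs)
    history = build_history_graph(steps, ctx)
    specimen_edges = {
        (i.iri, o.iri) for s in steps for i in s.inputs for o in s.outputs
    }

    # --- assays ------------------------------------------------------------
    description_graphs = parthood_graphs + quality_graphs + measurement_graphs
    desc_iris = [g.iri for g in description_graphs]
    shuffled = desc_iris[:]
    rng.shuffle(shuffled)
    n_assays = min(len(leaves), len(shuffled))
    assay_cls = terms.get("obi", "microscopy assay")
    assay_graphs: list[NamedGraph] = []
    assay_of_graph: dict[Iri, Iri] = {}
    for k in range(n_assays):
        outputs = shuffled[k::n_assays]
        assay = ctx.new_instance(assay_cls)
        rec = AssayRecord(
            assay=assay,
            input_specimen=leaves[k],
            output_graphs=outputs,
            agent=ctx.new_instance(terms.get("ncbitaxon", "Homo sapiens"), "observer"),
            date="2018-06-12",
        )
        assay_graphs.append(build_assay_graph(rec, ctx))
        for g_iri in outputs:
            assay_of_graph[g_iri] = assay.iri

    # --- document + assertions --------------------------------------------
    assertions_iri = ctx.minter.mint("assertions")
    doc = ctx.new_instance(terms.get("iao", "document"), f"description document (seed {cfg.seed})")
    meta = DocumentMetadata(title=f"Synthetic morphological description {cfg.seed}")
    meta.sections["abstract"] = (
        f"A generated instance-based morphological description of {cfg.n_parts} parts."
    )
    doc_result = build_document_graph(meta, doc, assertions_iri, ctx)
    anatomy = ctx.new_instance(terms.get("ngo", "instance anatomy"))
    metadata_graphs = assay_graphs + [collection, history]
    assertions = build_assertions_graph(
        doc_result.sections["results"],
        doc_result.sections["methods"],
        anatomy,
        description_graphs,
        metadata_graphs,
        ctx,
        graph_iri=assertions_iri,
    )

    store.add_graphs([doc_result.graph, assertions])
    store.add_graphs(description_graphs)
    store.add_graphs(metadata_graphs)

    gt = GroundTruth(
        document=doc.iri,
        anatomy=anatomy.iri,
        assertions_graph=assertions.iri,
        results_section=doc_result.sections["results"].iri,
        methods_section=doc_result.sections["methods"].iri,
        root=root.iri,
        parts=parts,
        parthood_graph_of=parthood_graph_of,
        qualities=qualities,
        measurements=measurements,
        assay_of_graph=assay_of_graph,
        specimen_edges=specimen_edges,
        description_graphs=desc_iris,
        metadata_graphs=[g.iri for g in metadata_graphs],
    )
    return store, doc.iri, gt


def monolithic_description(gt: GroundTruth, predicates: Optional[PredicateTable] = None) -> set[Statement]:
    """The same description as one flat statement set, enumerated directly
    from the ground truth without the builders or the store: the reference
    for the fragmentation-is-lossless property."""
    p = predicates or PredicateTable()
    out: set[Statement] = set()
    for t in gt.parts.values():
        out.add(Statement(t.iri, p.rdf_type, t.class_ref.iri))
        out.add(Statement(t.iri, p.rdfs_label, Literal(t.label)))
        if t.parent is not None:
            out.add(Statement(t.parent, p.has_part, t.iri))
    for q in gt.qualities:
        out.add(Statement(q.bearer, p.has_quality, q.quality))
        out.add(Statement(q.quality, p.rdf_type, q.quality_class.iri))
    for m in gt.measurements:
        out.add(Statement(m.bearer, p.has_quality, m.quality))
        out.add(Statement(m.quality, p.rdf_type, m.quality_class.iri))
        out.add(Statement(m.quality, p.has_value, Literal.of_float(m.value)))
        out.add(Statement(m.quality, p.has_unit, m.unit_instance))
        out.add(Statement(m.unit_instance, p.rdf_type, m.unit_class.iri))
    return out


def paper_example() -> tuple[QuadStore, Iri]:
    """The fixed worked example: adult hymenopteran with head and thorax, a
    0.25 ml head volume, a rugose thorax surface texture, one microscopy
    assay grounding all five description graphs, a live-trap collection
    record, and a forked specimen history (A → B, B → C + D)."""
    store = QuadStore()
    ctx = BuilderContext(IriMinter("https://example.org/worked-example/", 0))
    ctx.terms = store.terms
    ctx.ng_classes = store.ng_classes
    ctx.predicates = store.predicates
    terms = ctx.terms

    adult = ctx.new_instance(terms.get("hao", "adult"), "specimen A, whole organism")
    head = ctx.new_instance(terms.get("hao", "head"), "head of specimen A")
    thorax = ctx.new_instance(terms.get("hao", "thorax"), "thorax of specimen A")
    g_root = build_root_parthood_graph(adult, ctx)
    g_head = build_parthood_graph(adult, head, ctx)
    g_thorax = build_parthood_graph(adult, thorax, ctx)
    g_texture = build_quality_graph(
        QualityRecord(thorax, terms.get("pato", "rugose"), "anatomical-surface-texture"), ctx
    )
    g_volume = build_measurement_graph(
        MeasurementRecord(
            head, terms.get("pato", "volume"), 0.25,
            terms.get("uo", "milliliter"), "anatomical-structure-volume",
        ),
        ctx,
    )

    specimen_cls = terms.get("obi", "specimen")
    s_a = ctx.new_instance(specimen_cls, "specimen A")
    s_b = ctx.new_instance(specimen_cls, "specimen B")
    s_c = ctx.new_instance(specimen_cls, "specimen C")
    s_d = ctx.new_instance(specimen_cls, "specimen D")
    g_collection = build_collection_graph(
        CollectionRecord(
            process=ctx.new_instance(terms.get("obi", "specimen collection process")),
            input_material=ctx.new_instance(terms.get("bfo", "material entity"),
                                            "free-living organism"),
            output_specimen=s_a,
            device=ctx.new_instance(terms.get("obi", "device"), "live trap"),
            date="2018-05-04",
        ),
        ctx,
    )
    processing = terms.get("obi", "material processing")
    g_history = build_history_graph(
        [
            ProcessingStep(ctx.new_instance(processing), (s_a,), (s_b,)),
            ProcessingStep(ctx.new_instance(processing), (s_b,), (s_c, s_d)),
        ],
        ctx,
    )
    description_graphs = [g_root, g_head, g_thorax, g_texture, g_volume]
    g_assay = build_assay_graph(
        AssayRecord(
            assay=ctx.new_instance(terms.get("obi", "microscopy assay")),
            input_specimen=s_c,
            output_graphs=[g.iri for g in description_graphs],
            agent=ctx.new_instance(terms.get("ncbitaxon", "Homo sapiens"), "observer"),
            device=ctx.new_instance(terms.get("obi", "device"), "light microscope"),
            date="2018-06-12",
        ),
        ctx,
    )

    assertions_iri = ctx.minter.mint("assertions")
    doc = ctx.new_instance(terms.get("iao", "document"),
                           "Morphological description of a hymenopteran specimen")
    meta = DocumentMetadata(title="Morphological description of a hymenopteran specimen")
    meta.sections["abstract"] = (
        "An instance-based semantic description of one hymenopteran specimen: "
        "partonomy, a thorax surface texture, and a head volume in milliliter."
    )
    doc_result = build_document_graph(meta, doc, assertions_iri, ctx)
    anatomy = ctx.new_instance(terms.get("ngo", "instance anatomy"))
    assertions = build_assertions_graph(
        doc_result.sections["results"],
        doc_result.sections["methods"],
        anatomy,
        description_graphs,
        [g_assay, g_collection, g_history],
        ctx,
        graph_iri=assertions_iri,
    )
    store.add_graphs([doc_result.graph, assertions])
    store.add_graphs(description_graphs)
    store.add_graphs([g_assay, g_collection, g_history])
    return store, doc.iri
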