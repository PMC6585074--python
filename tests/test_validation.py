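"""Scheme conformance, mutation kill, and document-level integrity."""

import pytest

from anatomykg import (
    QuadStore,
    build_measurement_graph,
    required_statements,
    validate_document,
    validate_named_graph,
)
from anatomykg.builders import MeasurementRecord
from anatomykg.core import Iri, NamedGraph, Statement, TermRef
from anatomykg.errors import CatalogError
from anatomykg.fixtures import FixtureConfig, generate_description
from anatomykg.validation import ValidationContext


def _without(store, graph_iri, stmt):
    """Copy of the store with one statement removed from one graph (the graph
    is dropped entirely if that empties it)."""
    out = QuadStore(store.predicates, store.ng_classes, store.terms)
    for g in store.graphs():
        if g.iri == graph_iri:
            rest = g.statements - {stmt}
            if rest:
                out.add_graph(NamedGraph(g.iri, g.ng_class, frozenset(rest)))
        else:
            out.add_graph(g)
    return out


class TestGraphSchemes:
    def test_every_builder_output_validates_cleanly(self, paper_store):
        store, _ = paper_store
        ctx = ValidationContext.from_store(store)
        for g in store.graphs():
            report = validate_named_graph(g, ctx)
            assert report.passed and not report.warnings, report.render()

    def test_unknown_graph_class_is_catalog_error(self, paper_store):
        store, _ = paper_store
        rogue = NamedGraph(
            Iri("https://t.example/g"),
            TermRef(Iri("https://t.example/NoSuchClass"), "mystery", "zz"),
            frozenset({Statement(Iri("https://t.example/s"),
                                 store.predicates.rdf_type,
                                 Iri("https://t.example/C"))}),
        )
        with pytest.raises(CatalogError):
            validate_named_graph(rogue, ValidationContext.from_store(store))

    def test_measurement_without_value_fails(self, ctx):
        g = build_measurement_graph(
            MeasurementRecord(
                ctx.new_instance(ctx.terms.get("hao", "head"), "head"),
                ctx.terms.get("pato", "volume"), 0.25, ctx.terms.get("uo", "milliliter")),
            ctx)
        (val,) = [st for st in g.statements if st.p == ctx.predicates.has_value]
        broken = NamedGraph(g.iri, g.ng_class, g.statements - {val})
        from anatomykg.validation import ValidationContext as VC

        vctx = VC(ctx.predicates, ctx.ng_classes, ctx.terms)
        report = validate_named_graph(broken, vctx)
        assert not report.passed
        assert any("measurement.value" == v.rule for v in report.errors)

    def test_doubled_parthood_edge_violates_one_statement_per_graph(self, paper_store):
        store, _ = paper_store
        p = store.predicates
        parthood_cls = store.ng_classes.term("parthood").iri
        child_graphs = [
            g for g in store.graphs()
            if g.ng_class.iri == parthood_cls
            and any(st.p == p.has_part for st in g.statements)
        ]
        g = child_graphs[0]
        (edge,) = [st for st in g.statements if st.p == p.has_part]
        doubled = NamedGraph(
            g.iri, g.ng_class,
            g.statements | {Statement(Iri(edge.s.value + "-other"), p.has_part, edge.o)})
        report = validate_named_graph(doubled, ValidationContext.from_store(store))
        assert any(v.rule == "parthood.single-edge" for v in report.errors)


class TestMutationKill:
    """Deleting any required statement from any graph of a generated document
    must flip document validation to failing; deleting a non-required one
    must never produce a silently identical report."""

    @pytest.mark.parametrize("seed", [2, 9])
    def test_required_statement_deletion_flips_validation(self, seed):
        store, doc, _gt = generate_description(
            FixtureConfig(seed=seed, n_parts=4, n_specimens=2))
        assert validate_document(store, doc).passed
        ctx = ValidationContext.from_store(store)
        for g in store.graphs():
            required = required_statements(g, ctx)
            for st in sorted(g.statements):
                report = validate_document(_without(store, g.iri, st), doc)
                if st in required:
                    assert not report.passed, (
                        f"deleting ({st.s}, {st.p}, {st.o}) from {g.ng_class.label} "
                        "should have failed validation")
                # non-required statements are tolerated by design (labels,
                # dates, free text, redundant assay coverage)

    def test_optional_assay_output_deletion_downgrades_to_warning(self, paper_store):
        store, doc = paper_store
        p = store.predicates
        assay_cls = store.ng_classes.term("assay-data").iri
        (assay_graph,) = [g for g in store.graphs() if g.ng_class.iri == assay_cls]
        outputs = [st for st in assay_graph.statements if st.p == p.has_specified_output]
        assert len(outputs) > 1
        report = validate_document(_without(store, assay_graph.iri, outputs[0]), doc)
        assert report.passed
        assert any(v.rule == "doc.no-provenance" for v in report.warnings)


class TestDocumentIntegrity:
    def test_generated_documents_validate(self):
        for seed in (0, 1, 2):
            store, doc, _ = generate_description(FixtureConfig(seed=seed))
            report = validate_document(store, doc)
            assert report.passed, report.render()

    def test_deleting_a_parthood_graph_is_dangling_reference(self, paper_store):
        store, doc = paper_store
        parthood_cls = store.ng_classes.term("parthood").iri
        victim = [g for g in store.graphs() if g.ng_class.iri == parthood_cls][1]
        pruned = QuadStore(store.predicates, store.ng_classes, store.terms)
        for g in store.graphs():
            if g.iri != victim.iri:
                pruned.add_graph(g)
        report = validate_document(pruned, doc)
        assert not report.passed
        assert any(v.rule == "doc.dangling-graph" for v in report.errors)

    def test_assay_output_outside_description_list_is_error(self, paper_store):
        store, doc = paper_store
        p = store.predicates
        assay_cls = store.ng_classes.term("assay-data").iri
        (assay_graph,) = [g for g in store.graphs() if g.ng_class.iri == assay_cls]
        (assay,) = {st.s for st in assay_graph.statements
                    if st.p == p.has_specified_output}
        stray = Statement(assay, p.has_specified_output,
                          Iri("https://t.example/not-a-description-graph"))
        patched = QuadStore(store.predicates, store.ng_classes, store.terms)
        for g in store.graphs():
            if g.iri == assay_graph.iri:
                patched.add_graph(NamedGraph(g.iri, g.ng_class, g.statements | {stray}))
            else:
                patched.add_graph(g)
        report = validate_document(patched, doc)
        assert any(v.rule == "doc.assay-output-unlisted" for v in report.errors)

    def test_reports_are_deterministic_and_ordered(self, paper_store):
        store, doc = paper_store
        r1 = validate_document(store, doc)
        r2 = validate_document(store, doc)
        assert [v.sort_key() for v in r1.violations] == sorted(
            v.sort_key() for v in r2.violations)
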