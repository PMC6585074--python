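"""Each builder emits exactly the statements its graph class's scheme
mandates; the counts below are enumerated by hand from the schemes."""

import pytest

from anatomykg import (
    AssayRecord,
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
from anatomykg.core import Literal
from anatomykg.errors import CatalogError, CycleError, IntegrityError, SchemeError


def _doc(ctx, label="doc"):
    return ctx.new_instance(ctx.terms.get("iao", "document"), label)


def _part(ctx, label, term=("hao", "head")):
    return ctx.new_instance(ctx.terms.get(*term), label)


class TestDocumentGraph:
    def test_all_sections_no_text_is_nineteen_triples(self, ctx):
        # 1 doc type + 8 sections x (type + has_part) + assertions (type + link)
        res = build_document_graph(DocumentMetadata("t"), _doc(ctx),
                                   ctx.minter.mint("assertions"), ctx)
        assert len(res.graph) == 19

    def test_section_text_adds_exactly_one_literal(self, ctx):
        meta = DocumentMetadata("t")
        meta.sections["abstract"] = "short abstract"
        res = build_document_graph(meta, _doc(ctx), ctx.minter.mint("assertions"), ctx)
        assert len(res.graph) == 20

    def test_missing_results_section_is_scheme_error(self, ctx):
        meta = DocumentMetadata("t")
        del meta.sections["results"]
        with pytest.raises(SchemeError):
            build_document_graph(meta, _doc(ctx), ctx.minter.mint("assertions"), ctx)


class TestParthoodGraphs:
    def test_root_graph_is_type_plus_label_only(self, ctx):
        g = build_root_parthood_graph(_part(ctx, "specimen A whole organism", ("hao", "adult")), ctx)
        assert len(g) == 2
        assert not [st for st in g.statements if st.p == ctx.predicates.has_part]

    def test_child_graph_has_three_statements_including_edge(self, ctx):
        organism = _part(ctx, "organism", ("hao", "adult"))
        head = _part(ctx, "head")
        g = build_parthood_graph(organism, head, ctx)
        assert len(g) == 3
        (edge,) = [st for st in g.statements if st.p == ctx.predicates.has_part]
        assert (edge.s, edge.o) == (organism.iri, head.iri)

    def test_self_parthood_rejected(self, ctx):
        head = _part(ctx, "head")
        with pytest.raises(CycleError):
            build_parthood_graph(head, head, ctx)

    def test_unlabeled_part_rejected(self, ctx):
        with pytest.raises(SchemeError):
            build_root_parthood_graph(_part(ctx, None), ctx)

    def test_union_of_root_and_three_children_is_eleven(self, ctx):
        root = _part(ctx, "organism", ("hao", "adult"))
        graphs = [build_root_parthood_graph(root, ctx)]
        for name in ("head", "mesosoma", "metasoma"):
            graphs.append(build_parthood_graph(root, _part(ctx, name, ("hao", name)), ctx))
        union = set().union(*(g.statements for g in graphs))
        assert len(union) == 2 + 3 * 3

    def test_distinct_roots_share_no_subject(self, ctx):
        g1 = build_root_parthood_graph(_part(ctx, "a", ("hao", "adult")), ctx)
        g2 = build_root_parthood_graph(_part(ctx, "b", ("hao", "adult")), ctx)
        assert {st.s for st in g1.statements}.isdisjoint(st.s for st in g2.statements)


class TestQualityAndMeasurement:
    def test_quality_graph_is_two_statements(self, ctx):
        g = build_quality_graph(
            QualityRecord(_part(ctx, "thorax surface", ("hao", "thorax")),
                          ctx.terms.get("pato", "rugose")), ctx)
        assert len(g) == 2

    def test_two_quality_records_mint_distinct_quality_instances(self, ctx):
        bearer = _part(ctx, "thorax")
        g1 = build_quality_graph(QualityRecord(bearer, ctx.terms.get("pato", "rugose")), ctx)
        g2 = build_quality_graph(QualityRecord(bearer, ctx.terms.get("pato", "smooth")), ctx)
        q = ctx.predicates.has_quality
        q1 = {st.o for st in g1.statements if st.p == q}
        q2 = {st.o for st in g2.statements if st.p == q}
        assert g1.iri != g2.iri and q1.isdisjoint(q2)

    def test_unregistered_category_is_catalog_error(self, ctx):
        with pytest.raises(CatalogError):
            build_quality_graph(
                QualityRecord(_part(ctx, "x"), ctx.terms.get("pato", "rugose"),
                              category="anatomical-surface-colour"), ctx)

    def test_measurement_graph_is_five_statements_with_float(self, ctx):
        g = build_measurement_graph(
            MeasurementRecord(_part(ctx, "head"), ctx.terms.get("pato", "volume"),
                              0.25, ctx.terms.get("uo", "milliliter")), ctx)
        assert len(g) == 5
        (val,) = [st.o for st in g.statements if st.p == ctx.predicates.has_value]
        assert isinstance(val, Literal) and float(val.lexical) == 0.25

    def test_nan_value_rejected(self, ctx):
        with pytest.raises(SchemeError):
            build_measurement_graph(
                MeasurementRecord(_part(ctx, "head"), ctx.terms.get("pato", "volume"),
                                  float("nan"), ctx.terms.get("uo", "milliliter")), ctx)

    def test_two_measurements_share_only_the_bearer(self, ctx):
        bearer = _part(ctx, "head")
        rec = MeasurementRecord(bearer, ctx.terms.get("pato", "volume"), 1.0,
                                ctx.terms.get("uo", "milliliter"))
        g1, g2 = build_measurement_graph(rec, ctx), build_measurement_graph(rec, ctx)
        shared = {st.s for st in g1.statements} & {st.s for st in g2.statements}
        assert shared == {bearer.iri}


def _specimen(ctx, label):
    return ctx.new_instance(ctx.terms.get("obi", "specimen"), label)


class TestProcessGraphs:
    def test_assay_with_agent_and_device_is_eight_statements(self, ctx):
        # base (type + input link) + 2 output links + 2x (aux type + link);
        # aux instances unlabeled
        rec = AssayRecord(
            assay=ctx.new_instance(ctx.terms.get("obi", "microscopy assay")),
            input_specimen=_specimen(ctx, "specimen C"),
            output_graphs=[ctx.minter.mint("parthood"), ctx.minter.mint("parthood")],
            agent=ctx.new_instance(ctx.terms.get("ncbitaxon", "Homo sapiens")),
            device=ctx.new_instance(ctx.terms.get("obi", "device")),
        )
        assert len(build_assay_graph(rec, ctx)) == 2 + 2 + 2 * 2

    def test_staining_substance_adds_type_plus_input_link(self, ctx):
        base = AssayRecord(
            assay=ctx.new_instance(ctx.terms.get("obi", "microscopy assay")),
            input_specimen=_specimen(ctx, "s"),
            output_graphs=[ctx.minter.mint("parthood")],
        )
        plain = build_assay_graph(base, ctx)
        base.extra_inputs = [ctx.new_instance(ctx.terms.get("bfo", "material entity"))]
        assert len(build_assay_graph(base, ctx)) == len(plain) + 2

    def test_assay_without_outputs_rejected(self, ctx):
        with pytest.raises(SchemeError):
            build_assay_graph(AssayRecord(
                assay=ctx.new_instance(ctx.terms.get("obi", "microscopy assay")),
                input_specimen=_specimen(ctx, "s"), output_graphs=[]), ctx)

    def test_minimal_collection_is_five_statements(self, ctx):
        rec = CollectionRecord(
            process=ctx.new_instance(ctx.terms.get("obi", "specimen collection process")),
            input_material=ctx.new_instance(ctx.terms.get("bfo", "material entity")),
            output_specimen=_specimen(ctx, "specimen A"),
        )
        assert len(build_collection_graph(rec, ctx)) == 5

    def test_live_trap_and_date_add_four(self, ctx):
        rec = CollectionRecord(
            process=ctx.new_instance(ctx.terms.get("obi", "specimen collection process")),
            input_material=ctx.new_instance(ctx.terms.get("bfo", "material entity")),
            output_specimen=_specimen(ctx, "specimen A"),
            device=ctx.new_instance(ctx.terms.get("obi", "device"), "live trap"),
            date="2018-05-04",
        )
        # device: type + link + label; date: one literal
        assert len(build_collection_graph(rec, ctx)) == 5 + 3 + 1


class TestHistoryGraph:
    def test_linear_chain(self, ctx):
        a, b, c = (_specimen(ctx, s) for s in "ABC")
        proc = lambda: ctx.new_instance(ctx.terms.get("obi", "material processing"))
        g = build_history_graph(
            [ProcessingStep(proc(), (a,), (b,)), ProcessingStep(proc(), (b,), (c,))], ctx)
        p = ctx.predicates
        specimens = {st.s for st in g.statements
                     if st.p == p.rdf_type and st.o == ctx.terms.get("obi", "specimen").iri}
        assert specimens == {a.iri, b.iri, c.iri}

    def test_fork_reaches_both_outputs(self, ctx):
        a, tissue, voucher = (_specimen(ctx, s) for s in ("A", "tissue sample", "voucher"))
        step = ProcessingStep(
            ctx.new_instance(ctx.terms.get("obi", "material processing")),
            (a,), (tissue, voucher))
        g = build_history_graph([step], ctx)
        outs = {st.o for st in g.statements if st.p == ctx.predicates.has_specified_output}
        assert outs == {tissue.iri, voucher.iri}

    def test_cycle_rejected(self, ctx):
        a, b = _specimen(ctx, "A"), _specimen(ctx, "B")
        proc = lambda: ctx.new_instance(ctx.terms.get("obi", "material processing"))
        with pytest.raises(CycleError):
            build_history_graph(
                [ProcessingStep(proc(), (a,), (b,)), ProcessingStep(proc(), (b,), (a,))], ctx)


class TestAssertionsGraph:
    def _anatomy(self, ctx):
        return ctx.new_instance(ctx.terms.get("ngo", "instance anatomy"))

    def _sections(self, ctx):
        res = build_document_graph(DocumentMetadata("t"), _doc(ctx),
                                   ctx.minter.mint("assertions"), ctx)
        return res.sections["results"], res.sections["methods"]

    def _graphs(self, ctx, n_desc, n_meta):
        root = _part(ctx, "organism", ("hao", "adult"))
        desc = [build_root_parthood_graph(root, ctx)]
        for i in range(n_desc - 1):
            desc.append(build_parthood_graph(root, _part(ctx, f"head {i}"), ctx))
        meta = []
        for i in range(n_meta):
            meta.append(build_collection_graph(CollectionRecord(
                process=ctx.new_instance(ctx.terms.get("obi", "specimen collection process")),
                input_material=ctx.new_instance(ctx.terms.get("bfo", "material entity")),
                output_specimen=_specimen(ctx, f"s{i}")), ctx))
        return desc, meta

    def test_four_desc_two_meta_is_fourteen(self, ctx):
        results, methods = self._sections(ctx)
        desc, meta = self._graphs(ctx, 4, 2)
        g = build_assertions_graph(results, methods, self._anatomy(ctx), desc, meta, ctx)
        assert len(g) == 2 + 4 * 2 + 2 * 2

    def test_duplicate_listing_collapses_by_set_semantics(self, ctx):
        results, methods = self._sections(ctx)
        desc, _ = self._graphs(ctx, 2, 0)
        once = build_assertions_graph(results, methods, self._anatomy(ctx), desc, [], ctx)
        twice = build_assertions_graph(results, methods, self._anatomy(ctx), desc + desc, [], ctx)
        assert len(once) == len(twice)

    def test_graph_in_both_lists_rejected(self, ctx):
        results, methods = self._sections(ctx)
        desc, _ = self._graphs(ctx, 1, 0)
        with pytest.raises(IntegrityError):
            build_assertions_graph(results, methods, self._anatomy(ctx), desc, desc, ctx)
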