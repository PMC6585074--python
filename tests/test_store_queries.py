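"""Quad store, locate templates, unions, and partonomy extraction — each
checked against a brute-force quad scan and against generator ground truth."""

import pytest

from anatomykg import (
    QuadStore,
    TriplePattern,
    build_root_parthood_graph,
    description_union,
    extract_partonomy,
    locate_assertions_graph,
    locate_document_graph,
    locate_instance_anatomy,
    metadata_union,
    parthood_union,
    union_graphs,
)
from anatomykg.core import Iri, NamedGraph, Statement
from anatomykg.errors import (
    AmbiguityError,
    CollisionError,
    ConfigurationError,
    CycleError,
    DanglingReferenceError,
    MalformedPartonomyError,
    NotFoundError,
)
from anatomykg.fixtures import FixtureConfig, generate_description

from conftest import oracle_find_graphs, oracle_union


class TestStoreBasics:
    def test_add_then_get_round_trips(self, ctx):
        g = build_root_parthood_graph(
            ctx.new_instance(ctx.terms.get("hao", "adult"), "organism"), ctx)
        store = QuadStore()
        store.add_graph(g)
        assert store.get_graph(g.iri).statements == g.statements

    def test_duplicate_iri_rejected_unless_replace(self, ctx):
        g = build_root_parthood_graph(
            ctx.new_instance(ctx.terms.get("hao", "adult"), "organism"), ctx)
        store = QuadStore().add_graph(g)
        with pytest.raises(CollisionError):
            store.add_graph(g)
        store.add_graph(g, replace=True)

    def test_quad_count_is_sum_of_statement_counts(self, paper_store):
        store, _ = paper_store
        assert store.quad_count() == sum(len(g) for g in store.graphs())

    def test_pattern_requires_a_bound_position(self):
        with pytest.raises(ConfigurationError):
            TriplePattern()


class TestPatternQueries:
    def test_find_graphs_agrees_with_brute_force(self, paper_store):
        store, doc = paper_store
        p = store.predicates
        patterns = [
            TriplePattern(doc, p.rdf_type, store.terms.get("iao", "document").iri),
            TriplePattern(None, p.has_part, None),
            TriplePattern(None, p.rdf_type, store.terms.get("obi", "specimen").iri),
            TriplePattern(None, p.has_quality, None),
            TriplePattern(Iri("https://nowhere.example/x"), None, None),
        ]
        for pat in patterns:
            assert store.find_graphs_containing(pat) == oracle_find_graphs(store, pat)

    def test_results_are_sorted_and_deterministic(self, paper_store):
        store, _ = paper_store
        hits = store.find_graphs_containing(TriplePattern(p=store.predicates.rdf_type))
        assert hits == sorted(hits)


class TestLocateTemplates:
    def test_two_step_lookup_on_fixture(self, paper_store):
        store, doc = paper_store
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        # oracle route: scan quads for the same type triples
        p = store.predicates
        doc_cls = store.terms.get("iao", "document").iri
        assert [dg] == oracle_find_graphs(store, TriplePattern(doc, p.rdf_type, doc_cls))
        ia_cls = store.terms.get("ngo", "instance anatomy").iri
        brute = sorted(
            q.statement.s for q in store.quads()
            if q.graph == ag and q.statement.p == p.rdf_type and q.statement.o == ia_cls
        )
        assert brute == [anatomy]

    def test_unknown_document_not_found(self, paper_store):
        store, _ = paper_store
        with pytest.raises(NotFoundError):
            locate_document_graph(store, Iri("https://nowhere.example/doc"))

    def test_document_typed_in_two_graphs_is_ambiguous(self, paper_store, ctx):
        store, doc = paper_store
        clone = QuadStore(store.predicates, store.ng_classes, store.terms)
        for g in store.graphs():
            clone.add_graph(g)
        extra = NamedGraph(
            Iri("https://test.example/extra-doc-graph"),
            store.ng_classes.term("document"),
            frozenset({Statement(doc, store.predicates.rdf_type,
                                 store.terms.get("iao", "document").iri)}),
        )
        clone.add_graph(extra)
        with pytest.raises(AmbiguityError):
            locate_document_graph(clone, doc)


class TestUnions:
    def test_union_is_idempotent_and_additive(self, paper_store):
        store, _ = paper_store
        iris = store.graph_iris()[:3]
        assert union_graphs(store, [iris[0], iris[0]]) == store.get_graph(iris[0]).statements
        disjoint = union_graphs(store, iris)
        assert disjoint == oracle_union(store, iris)

    def test_union_of_dangling_iri_raises(self, paper_store):
        store, _ = paper_store
        with pytest.raises(DanglingReferenceError):
            union_graphs(store, [Iri("https://nowhere.example/g")])

    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_unions_agree_with_brute_force_scan(self, seed):
        store, doc, gt = generate_description(FixtureConfig(seed=seed, n_parts=7))
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        p = store.predicates
        parthood_cls = store.ng_classes.term("parthood").iri
        # oracle: scan the assertions graph's quads for part links + types
        links = {q.statement.o for q in store.quads()
                 if q.graph == ag and q.statement.s == anatomy
                 and q.statement.p == p.has_part}
        typed_parthood = {q.statement.s for q in store.quads()
                          if q.graph == ag and q.statement.p == p.rdf_type
                          and q.statement.o == parthood_cls}
        assert parthood_union(store, anatomy, ag) == oracle_union(
            store, links & typed_parthood)
        assert description_union(store, anatomy, ag) == oracle_union(store, links)
        meta_links = {q.statement.o for q in store.quads()
                      if q.graph == ag and q.statement.s == gt.methods_section
                      and q.statement.p == p.has_part}
        assert metadata_union(store, gt.methods_section, ag) == oracle_union(store, meta_links)

    def test_parthood_union_excludes_measurement_graphs(self, paper_store):
        store, doc = paper_store
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        pu = parthood_union(store, anatomy, ag)
        assert not [st for st in pu if st.p == store.predicates.has_value]
        # worked example: root (2) + two children (3 each)
        assert len(pu) == 2 + 3 + 3

    def test_description_union_supersets_parthood_union(self, paper_store):
        store, doc = paper_store
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        assert parthood_union(store, anatomy, ag) <= description_union(store, anatomy, ag)

    def test_metadata_union_disjoint_from_part_subjects(self, generated):
        store, doc, gt = generated
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        part_subjects = {st.s for st in parthood_union(store, anatomy, ag)}
        meta_subjects = {st.s for st in metadata_union(store, gt.methods_section, ag)}
        assert part_subjects.isdisjoint(meta_subjects)


class TestPartonomyExtraction:
    def test_recovers_generating_tree_exactly(self, generated):
        store, doc, gt = generated
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        tree = extract_partonomy(parthood_union(store, anatomy, ag), store.predicates)
        assert tree.root == gt.root
        assert tree.parent_map() == gt.parent_map()
        assert tree.labels == {t.iri: t.label for t in gt.parts.values()}

    def test_large_random_tree_recovery(self):
        store, doc, gt = generate_description(
            FixtureConfig(seed=101, n_parts=1000, max_depth=12,
                          p_texture=0.0, p_measurement=0.0))
        dg = locate_document_graph(store, doc)
        ag = locate_assertions_graph(store, dg)
        anatomy = locate_instance_anatomy(store, ag)
        tree = extract_partonomy(parthood_union(store, anatomy, ag), store.predicates)
        assert tree.parent_map() == gt.parent_map()
        assert len(tree.nodes) == 1000

    def test_root_only_partonomy(self, ctx):
        g = build_root_parthood_graph(
            ctx.new_instance(ctx.terms.get("hao", "adult"), "organism"), ctx)
        tree = extract_partonomy(set(g.statements), ctx.predicates)
        assert tree.edges == set() and tree.depth() == 1

    def test_cycle_and_double_root_rejected(self, ctx):
        p = ctx.predicates
        a, b = Iri("https://t.example/a"), Iri("https://t.example/b")
        cyc = {Statement(a, p.has_part, b), Statement(b, p.has_part, a)}
        with pytest.raises(CycleError):
            extract_partonomy(cyc, p)
        c, d = Iri("https://t.example/c"), Iri("https://t.example/d")
        two_roots = {Statement(a, p.has_part, b), Statement(c, p.has_part, d)}
        with pytest.raises(MalformedPartonomyError):
            extract_partonomy(two_roots, p)
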