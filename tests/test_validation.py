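"""Validation rules and inverse-property algebra."""

import pytest

from conftest import synth_graph
from tmaowl.identifiers import Iri
from tmaowl.rdf_io import Literal, OWL_CLASS, RDF_TYPE, TmaGraph, Triple
from tmaowl.schema import TMA_NS
from tmaowl.validation import (
    InverseConsistencyError,
    materialize_inverses,
    strip_inverses,
    validate,
)

BASE = "http://x.org/doc.rdf"


def tiny_graph(*extra):
    """A minimal valid block+slide document, plus optional extra triples."""
    block = Iri(f"{BASE}#b1")
    slide = Iri(f"{BASE}#s1")
    triples = [
        Triple(block, RDF_TYPE, Iri(TMA_NS + "block")),
        Triple(slide, RDF_TYPE, Iri(TMA_NS + "slide")),
        Triple(block, Iri(TMA_NS + "includes_slide"), slide),
    ]
    g = TmaGraph(triples + list(extra))
    g.nsmap = g.nsmap.with_base(BASE)
    return g


class TestRules:
    def test_worked_example_is_valid(self, worked_graph):
        report = validate(worked_graph)
        assert report.valid
        assert report.errors() == []

    @pytest.mark.parametrize("seed", range(4))
    def test_synthetic_documents_are_valid(self, seed):
        assert validate(synth_graph(seed)).valid

    def test_untyped_edge_subject_is_e1(self):
        g = tiny_graph(Triple(Iri(f"{BASE}#ghost"),
                              Iri(TMA_NS + "includes_slide"), Iri(f"{BASE}#s1")))
        report = validate(g)
        assert not report.valid and report.by_rule("E1")

    def test_domain_violation_is_e2(self):
        tma = Iri("http://x.org/tma/1")
        g = tiny_graph(
            Triple(tma, RDF_TYPE, Iri(TMA_NS + "tma")),
            Triple(tma, Iri(TMA_NS + "slide_includes_core"), Iri(f"{BASE}#s1")),
        )
        report = validate(g)
        assert not report.valid and report.by_rule("E2")

    def test_internal_typed_range_violation_is_e3(self):
        g = tiny_graph(
            Triple(Iri(f"{BASE}#s1"), Iri(TMA_NS + "slide_includes_core"),
                   Iri(f"{BASE}#b1")),
        )
        report = validate(g)
        assert report.by_rule("E3")

    def test_object_property_with_literal_is_e3(self):
        g = tiny_graph(
            Triple(Iri(f"{BASE}#b1"), Iri(TMA_NS + "includes_slide"),
                   Literal("slide 58")),
        )
        assert validate(g).by_rule("E3")

    def test_dangling_internal_fragment_is_e4(self):
        g = tiny_graph(
            Triple(Iri(f"{BASE}#b1"), Iri(TMA_NS + "block_includes_core"),
                   Iri(f"{BASE}#coreZ9")),
        )
        report = validate(g)
        assert not report.valid
        assert any("coreZ9" in f.node for f in report.by_rule("E4"))

    def test_abstract_typing_is_e5(self):
        g = tiny_graph(
            Triple(Iri(f"{BASE}#p"), RDF_TYPE,
                   Iri(TMA_NS + "repository_product")),
        )
        assert validate(g).by_rule("E5")

    def test_external_references_are_warnings_not_errors(self):
        g = tiny_graph(
            Triple(Iri(f"{BASE}#b1"), Iri(TMA_NS + "included_in_tma"),
                   Iri("http://elsewhere.org/tma/9")),
        )
        report = validate(g)
        assert report.valid
        assert report.by_rule("W5")

    def test_legacy_typing_predicate_is_w1_only(self):
        block = Iri(f"{BASE}#b1")
        g = TmaGraph([Triple(block, OWL_CLASS, Iri(TMA_NS + "block"))])
        g.nsmap = g.nsmap.with_base(BASE)
        report = validate(g)
        assert report.valid and report.by_rule("W1")

    def test_odd_location_and_drill_site_shapes_warned(self):
        core = Iri(f"{BASE}#c1")
        g = tiny_graph(
            Triple(core, RDF_TYPE, Iri(TMA_NS + "core_on_slide")),
            Triple(core, Iri(TMA_NS + "location"), Literal("row 4, col D")),
            Triple(core, Iri(TMA_NS + "drill_site"), Literal("78;90")),
        )
        report = validate(g)
        assert report.valid
        assert report.by_rule("W2") and report.by_rule("W3")

    def test_validate_does_not_mutate_input(self, worked_graph):
        before = set(worked_graph.triples)
        validate(worked_graph)
        assert worked_graph.triples == before

    def test_report_json_shape(self):
        import json

        report = validate(tiny_graph())
        payload = json.loads(report.to_json())
        assert payload["valid"] is True
        assert isinstance(payload["findings"], list)


class TestInverseAlgebra:
    def test_materialization_adds_bottom_up_mirror(self):
        g = tiny_graph()
        out = materialize_inverses(g)
        mirror = Triple(Iri(f"{BASE}#s1"), Iri(TMA_NS + "cut_from_block"),
                        Iri(f"{BASE}#b1"))
        assert mirror in out
        assert g.triples < out.triples

    def test_empty_graph_unchanged(self):
        assert len(materialize_inverses(TmaGraph())) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotence(self, seed):
        g = synth_graph(seed)
        once = materialize_inverses(g)
        assert materialize_inverses(once).triples == once.triples

    @pytest.mark.parametrize("seed", range(4))
    def test_pair_symmetry_after_materialization(self, seed, vocab):
        g = materialize_inverses(synth_graph(seed))
        ns = vocab.namespace
        for t in g.triples:
            local = str(t.predicate)[len(ns):] if str(t.predicate).startswith(ns) else None
            if local and vocab.has_property(local):
                prop = vocab.property(local)
                if prop.kind == "object" and prop.inverse:
                    assert Triple(t.object, Iri(ns + prop.inverse), t.subject) in g

    @pytest.mark.parametrize("keep", ["top_down", "bottom_up"])
    @pytest.mark.parametrize("seed", range(3))
    def test_strip_then_materialize_recovers(self, seed, keep):
        full = materialize_inverses(synth_graph(seed))
        stripped = strip_inverses(full, keep=keep)
        assert materialize_inverses(stripped).triples == full.triples

    def test_strip_keeps_only_requested_direction(self):
        full = materialize_inverses(tiny_graph())
        top = strip_inverses(full, keep="top_down")
        assert Triple(Iri(f"{BASE}#b1"), Iri(TMA_NS + "includes_slide"),
                      Iri(f"{BASE}#s1")) in top
        assert not any("cut_from_block" in str(t.predicate) for t in top)

    def test_strip_unpaired_graph_unchanged(self):
        core = Iri(f"{BASE}#c1")
        g = TmaGraph([
            Triple(core, RDF_TYPE, Iri(TMA_NS + "core_on_slide")),
            Triple(core, Iri(TMA_NS + "location"), Literal("D4")),
        ])
        assert strip_inverses(g, keep="top_down").triples == g.triples

    def test_strip_rejects_unmaterialized_graph(self):
        with pytest.raises(InverseConsistencyError):
            strip_inverses(tiny_graph(), keep="top_down")
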