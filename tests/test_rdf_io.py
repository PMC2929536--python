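"""Document parsing/serialization, canonical ordering, isomorphism."""

import random

import pytest
import rdflib.compare

from conftest import synth_graph
from tmaowl.identifiers import Iri, NamespaceMap
from tmaowl.rdf_io import (
    BNode,
    FormatError,
    Literal,
    ParseError,
    RDF_TYPE,
    TmaGraph,
    Triple,
    canonical_triples,
    graph_isomorphic,
    normalize_typing,
    parse_document,
    serialize,
    to_rdflib,
    triple_key,
)
from tmaowl.schema import TMA_NS


def test_worked_example_document_round_trips(worked_graph):
    data = serialize(worked_graph, "rdf-xml")
    parsed = parse_document(data, "rdf-xml")
    assert parsed.triples == worked_graph.triples
    drill = Triple(
        Iri(worked_graph.nsmap.base + "#coreD4"),
        Iri(TMA_NS + "drill_site"),
        Literal("78,90"),
    )
    assert drill in parsed


def test_empty_document_parses_to_empty_graph():
    data = serialize(TmaGraph(), "rdf-xml")
    assert len(parse_document(data, "rdf-xml")) == 0


@pytest.mark.parametrize("fmt", ["rdf-xml", "turtle"])
@pytest.mark.parametrize("seed", range(6))
def test_parse_serialize_isomorphic_on_synthetic_documents(seed, fmt):
    g = synth_graph(seed)
    assert graph_isomorphic(g, parse_document(serialize(g, fmt), fmt))


def test_duplicate_statements_collapse():
    t = Triple(Iri("http://x.org/a"), RDF_TYPE, Iri(TMA_NS + "tma"))
    g = TmaGraph([t, t])
    assert len(g) == 1


def test_serialization_is_deterministic(worked_graph):
    assert serialize(worked_graph, "rdf-xml") == serialize(worked_graph, "rdf-xml")
    assert serialize(worked_graph, "turtle") == serialize(worked_graph, "turtle")


def test_literals_survive_byte_exact(worked_graph):
    text = serialize(worked_graph, "turtle").decode()
    for literal in ("All-Purpose Tissue Array", "Generic Tissue Bank",
                    "78,90", "D4"):
        assert f'"{literal}"' in text


def test_unsupported_format_rejected(worked_graph):
    with pytest.raises(FormatError):
        serialize(worked_graph, "trig")
    with pytest.raises(FormatError):
        parse_document(b"", "trig")


def test_malformed_document_raises_parse_error():
    with pytest.raises(ParseError):
        parse_document(b"<rdf:RDF><broken", "rdf-xml")


class TestCanonicalOrder:
    def test_sorted_and_permutation_invariant(self, worked_graph):
        triples = canonical_triples(worked_graph)
        assert triples == sorted(triples, key=triple_key)
        shuffled = list(worked_graph.triples)
        random.Random(7).shuffle(shuffled)
        assert canonical_triples(TmaGraph(shuffled, worked_graph.nsmap)) == triples

    def test_singleton(self):
        t = Triple(Iri("http://x.org/a"), RDF_TYPE, Iri(TMA_NS + "tma"))
        assert canonical_triples(TmaGraph([t])) == [t]

    def test_blank_nodes_relabelled_deterministically(self):
        def graph(label):
            b = BNode(label)
            return TmaGraph([
                Triple(Iri("http://x.org/core"), Iri(TMA_NS + "clinical_annotation"), b),
                Triple(b, Iri(TMA_NS + "status"), Literal("recurrent")),
            ])

        assert canonical_triples(graph("n1")) == canonical_triples(graph("zz93"))


class TestIsomorphism:
    def test_identity(self, worked_graph):
        assert graph_isomorphic(worked_graph, worked_graph)

    def test_one_literal_difference_detected(self, worked_graph):
        other = TmaGraph(
            {
                t.with_object(Literal("D5"))
                if isinstance(t.object, Literal) and t.object.value == "D4"
                else t
                for t in worked_graph.triples
            },
            worked_graph.nsmap,
        )
        assert not graph_isomorphic(worked_graph, other)

    @pytest.mark.parametrize("n_bnodes", [1, 3, 5])
    def test_blank_node_renaming_is_isomorphic(self, n_bnodes):
        def graph(prefix):
            g = TmaGraph()
            for i in range(n_bnodes):
                b = BNode(f"{prefix}{i}")
                g.add(Triple(Iri(f"http://x.org/core{i}"),
                             Iri(TMA_NS + "clinical_annotation"), b))
                g.add(Triple(b, Iri(TMA_NS + "status"), Literal(f"s{i}")))
            return g

        g1, g2 = graph("a"), graph("b")
        assert graph_isomorphic(g1, g2)
        # independent oracle: rdflib's isomorphism over the same graphs
        assert rdflib.compare.isomorphic(to_rdflib(g1), to_rdflib(g2))

    def test_agrees_with_rdflib_on_negative_case(self, worked_graph):
        other = TmaGraph(set(list(worked_graph.triples)[:-1]), worked_graph.nsmap)
        assert not graph_isomorphic(worked_graph, other)
        assert not rdflib.compare.isomorphic(to_rdflib(worked_graph), to_rdflib(other))


def test_legacy_typing_predicate_normalized():
    legacy = TmaGraph([
        Triple(Iri("http://x.org/t"), Iri("http://www.w3.org/2002/07/owl#Class"),
               Iri(TMA_NS + "tma")),
    ])
    normalized, changed = normalize_typing(legacy)
    assert changed
    assert Triple(Iri("http://x.org/t"), RDF_TYPE, Iri(TMA_NS + "tma")) in normalized
    again, changed2 = normalize_typing(normalized)
    assert not changed2 and again.triples == normalized.triples


def test_base_declared_in_output_and_recovered(worked_graph):
    for fmt in ("rdf-xml", "turtle"):
        parsed = parse_document(serialize(worked_graph, fmt), fmt)
        assert parsed.nsmap.base == worked_graph.nsmap.base
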