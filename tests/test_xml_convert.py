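"""The XML dialect and its conversion to OWL instance documents."""

import pytest
from lxml import etree

from conftest import synth_model
from tmaowl.identifiers import Iri, NamespaceMap, UriPolicy
from tmaowl.model import to_graph
from tmaowl.rdf_io import Triple, graph_isomorphic, serialize
from tmaowl.schema import TMA_NS
from tmaowl.synth import render_xml
from tmaowl.validation import validate
from tmaowl.xml_convert import (
    ConversionConfig,
    DialectError,
    XmlParseError,
    convert,
    parse_tma_xml,
)

FIXTURE = b"""<?xml version='1.0' encoding='UTF-8'?>
<tma identifier="000001" title="All-Purpose Tissue Array" creator="Michael J. Becich">
  <block identifier="RP2008-325">
    <slide identifier="slide058">
      <core identifier="coreD4" location="D4"/>
    </slide>
    <core identifier="coreD4" drill_site="78,90"
          donor_block="http://www.institutionXYZ.org/block/RP2007-228"
          diagnosis_term="http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma">
      <repository>Generic Tissue Bank</repository>
    </core>
  </block>
</tma>
"""


def fixture_config(direction="top_down"):
    return ConversionConfig(
        policy=UriPolicy(authority="www.institutionXYZ.org",
                         path_templates={"tma": ["tma"], "block": ["block"]}),
        nsmap=NamespaceMap(base="http://www.the_url_here.org/tma_example1.rdf"),
        direction=direction,
    )


class TestDialectParsing:
    def test_minimal_document_has_four_entities(self):
        doc = parse_tma_xml(
            b'<tma identifier="t"><block identifier="b">'
            b'<slide identifier="s"><core identifier="c"/></slide>'
            b"</block></tma>"
        )
        assert doc.entity_count() == 4

    def test_fixture_entity_census(self):
        doc = parse_tma_xml(FIXTURE)
        # tma + block + slide + core-in-block + core-on-slide
        assert doc.entity_count() == 5
        assert doc.title == "All-Purpose Tissue Array"
        assert doc.blocks[0].cores[0].drill_site == "78,90"
        assert doc.blocks[0].slides[0].cores[0].location == "D4"

    def test_empty_tma_element(self):
        doc = parse_tma_xml(b'<tma identifier="t1"/>')
        assert doc.entity_count() == 1 and doc.blocks == []

    def test_core_directly_under_tma_rejected(self):
        with pytest.raises(DialectError):
            parse_tma_xml(b'<tma identifier="t"><core identifier="c"/></tma>')

    def test_duplicate_block_identifier_rejected(self):
        xml = (b'<tma identifier="t">'
               b'<block identifier="b"/><block identifier="b"/></tma>')
        with pytest.raises(DialectError):
            parse_tma_xml(xml)

    def test_missing_identifier_rejected(self):
        with pytest.raises(DialectError):
            parse_tma_xml(b'<tma identifier="t"><block/></tma>')

    def test_malformed_xml_rejected(self):
        with pytest.raises(XmlParseError):
            parse_tma_xml(b"<tma identifier='t'")

    def test_wrong_root_rejected(self):
        with pytest.raises(DialectError):
            parse_tma_xml(b'<array identifier="t"/>')

    def test_unknown_children_kept_as_annotation_candidates(self):
        doc = parse_tma_xml(
            b'<tma identifier="t"><block identifier="b">'
            b"<core identifier='c'><status>ok</status></core></block></tma>"
        )
        assert doc.blocks[0].cores[0].extra == {"status": ["ok"]}


class TestConversion:
    def test_fixture_produces_hierarchy_triple(self):
        graph = convert(parse_tma_xml(FIXTURE), fixture_config())
        assert Triple(
            Iri("http://www.institutionXYZ.org/tma/000001"),
            Iri(TMA_NS + "includes_block"),
            Iri("http://www.institutionXYZ.org/block/RP2008-325"),
        ) in graph

    def test_fixture_graph_is_valid(self):
        graph = convert(parse_tma_xml(FIXTURE), fixture_config())
        assert validate(graph).valid

    def test_section_linked_to_matching_block_core(self):
        graph = convert(parse_tma_xml(FIXTURE), fixture_config())
        base = graph.nsmap.base
        assert Triple(
            Iri(f"{base}#slide058-D4"),
            Iri(TMA_NS + "derived_from_core"),
            Iri(f"{base}#coreD4"),
        ) in graph

    def test_bottom_up_direction_emits_only_child_to_parent_edges(self):
        graph = convert(parse_tma_xml(FIXTURE), fixture_config("bottom_up"))
        preds = {str(t.predicate) for t in graph}
        assert TMA_NS + "cut_from_block" in preds
        assert TMA_NS + "includes_slide" not in preds

    def test_both_directions_doubles_hierarchy_edges(self):
        top = convert(parse_tma_xml(FIXTURE), fixture_config("top_down"))
        both = convert(parse_tma_xml(FIXTURE), fixture_config("both"))
        # 4 paired hierarchy edges in the fixture gain their mirrors
        assert len(both) == len(top) + 4

    def test_xml_without_slides_or_cores(self):
        graph = convert(
            parse_tma_xml(b'<tma identifier="t"><block identifier="b"/></tma>'),
            fixture_config(),
        )
        preds = sorted({str(t.predicate).rsplit("#")[-1] for t in graph})
        assert preds == ["includes_block", "type"]

    def test_conversion_is_deterministic(self):
        a = serialize(convert(parse_tma_xml(FIXTURE), fixture_config()))
        b = serialize(convert(parse_tma_xml(FIXTURE), fixture_config()))
        assert a == b

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_construction_equivalence(self, seed):
        model, graph = synth_model(seed)
        config = ConversionConfig(
            policy=UriPolicy(authority="www.example-tma.org",
                             path_templates={"tma": ["tma"], "block": ["block"]}),
            nsmap=graph.nsmap,
            direction="top_down",
        )
        converted = convert(parse_tma_xml(render_xml(model)), config)
        assert graph_isomorphic(converted, to_graph(model, graph.nsmap))

    def test_typing_triples_match_entity_count(self):
        doc = parse_tma_xml(FIXTURE)
        graph = convert(doc, fixture_config())
        typing = [t for t in graph if str(t.predicate).endswith("#type")]
        assert len(typing) == doc.entity_count()


def test_rendered_xml_validates_against_shipped_xsd():
    from importlib.resources import files

    model, _ = synth_model(1)
    xsd = etree.XMLSchema(etree.parse(str(files("tmaowl") / "data" / "tma.xsd")))
    doc = etree.fromstring(render_xml(model))
    xsd.assertValid(doc)
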