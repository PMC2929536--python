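"""Conversion of well-structured TMA XML into OWL instance documents.

Extraction from a data source proceeds in three steps: collect the data
(a database query), store it in a well-defined structure (an XML file
in the dialect below), and convert that structure into OWL.  This
module implements the last step as a programmatic transform.

The XML dialect mirrors the physical hierarchy::

    <tma identifier="000001" title="..." creator="..." repository="...">
      <block identifier="RP2008-325">
        <slide identifier="slide058">
          <core identifier="coreD4" location="D4"/>
        </slide>
        <core identifier="coreD4" drill_site="78,90"
              donor_block="http://.../block/RP2007-228">
          <repository>Generic Tissue Bank</repository>
        </core>
      </block>
    </tma>

Core elements nested under a slide denote cores *on* that slide; core
elements nested directly under a block denote cores *in* the block.  A
core on a slide is linked ``derived_from_core`` to the block core with
the same identifier.  Unknown child elements are carried through as
annotation-property candidates.  An XSD for the dialect ships with the
package (``tmaowl/data/tma.xsd``).

Identifiers follow the document's URI policy: the TMA and its blocks
get absolute identifiers under the publisher's authority (keyed by the
domain-meaningful identifier, e.g. a bank accession), while slides and
cores become fragments of the instance document itself, cores on slides
as slide-derived fragments (``#slide058-D4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal as TypingLiteral

from lxml import etree

from .identifiers import Iri, NamespaceMap, UriPolicy, percent_encode
from .rdf_io import RDF_TYPE, Literal, TmaGraph, Triple
from .schema import ANNOTATION_PROPERTY_NAMES, DC_NS, build_schema

__all__ = [
    "XmlCore",
    "XmlSlide",
    "XmlBlock",
    "TmaXmlDocument",
    "ConversionConfig",
    "XmlParseError",
    "DialectError",
    "ConversionError",
    "parse_tma_xml",
    "convert",
]


class XmlParseError(ValueError):
    """The input is not well-formed XML."""


class DialectError(ValueError):
    """Well-formed XML that violates the TMA dialect."""


class ConversionError(ValueError):
    """The XML could not be converted (e.g. identifier collision)."""


@dataclass
class XmlCore:
    identifier: str
    location: str | None = None
    drill_site: str | None = None
    donor_block: str | None = None
    diagnosis_term: str | None = None
    extra: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class XmlSlide:
    identifier: str
    cores: list[XmlCore] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class XmlBlock:
    identifier: str
    donor_block: str | None = None
    diagnosis_term: str | None = None
    slides: list[XmlSlide] = field(default_factory=list)
    cores: list[XmlCore] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class TmaXmlDocument:
    identifier: str
    title: str | None = None
    creator: str | None = None
    repository: str | None = None
    blocks: list[XmlBlock] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)

    def entity_count(self) -> int:
        n = 1 + len(self.blocks)
        for b in self.blocks:
            n += len(b.slides) + len(b.cores)
            n += sum(len(s.cores) for s in b.slides)
        return n


@dataclass
class ConversionConfig:
    """URI policy + namespace map (with base) + hierarchy direction."""

    policy: UriPolicy
    nsmap: NamespaceMap
    direction: TypingLiteral["top_down", "bottom_up", "both"] = "top_down"

    def __post_init__(self) -> None:
        if self.nsmap.base is None:
            raise ConversionError("conversion requires a document base IRI")
        if self.direction not in ("top_down", "bottom_up", "both"):
            raise ConversionError(f"unknown direction {self.direction!r}")


def _extras(element, known_attrs: set[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for child in element:
        if not isinstance(child.tag, str):
            continue  # comments / processing instructions
        if child.tag in ("block", "slide", "core"):
            continue
        text = (child.text or "").strip()
        out.setdefault(child.tag, []).append(text)
    return out


def _require_identifier(element, seen: set[str], kind: str) -> str:
    ident = element.get("identifier")
    if not ident:
        raise DialectError(f"<{element.tag}> element lacks an identifier")
    if ident in seen:
        raise DialectError(f"duplicate {kind} identifier {ident!r}")
    seen.add(ident)
    return ident


def _parse_core(element, seen: set[str], scope: str | None = None) -> XmlCore:
    # A core on a slide names the block core it derives from, so the
    # same identifier may recur across slides; its uniqueness key is
    # (slide, location or identifier).
    ident = element.get("identifier")
    if not ident:
        raise DialectError("<core> element lacks an identifier")
    key = ident if scope is None else (
        f"{scope}/{element.get('location') or ident}"
    )
    if key in seen:
        raise DialectError(f"duplicate core identifier {key!r}")
    seen.add(key)
    for child in element:
        if isinstance(child.tag, str) and child.tag in ("block", "slide", "core"):
            raise DialectError(f"<core> may not contain <{child.tag}>")
    return XmlCore(
        identifier=ident,
        location=element.get("location"),
        drill_site=element.get("drill_site"),
        donor_block=element.get("donor_block"),
        diagnosis_term=element.get("diagnosis_term"),
        extra=_extras(element, set()),
    )


def parse_tma_xml(data: bytes | str) -> TmaXmlDocument:
    """Parse and dialect-check a TMA XML document.

    Enforces the nesting ``tma > block > {slide, core}`` and
    ``slide > core``, and identifier uniqueness per element kind.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"malformed XML: {exc}") from exc
    if root.tag != "tma":
        raise DialectError(f"root element must be <tma>, found <{root.tag}>")
    doc = TmaXmlDocument(
        identifier=_require_identifier(root, set(), "tma"),
        title=root.get("title"),
        creator=root.get("creator"),
        repository=root.get("repository"),
        extra=_extras(root, set()),
    )
    seen_blocks: set[str] = set()
    seen_slides: set[str] = set()
    seen_block_cores: set[str] = set()
    seen_slide_cores: set[str] = set()
    for child in root:
        if not isinstance(child.tag, str):
            continue
        if child.tag in ("slide", "core"):
            raise DialectError(
                f"<{child.tag}> must be nested inside a <block>, not <tma>"
            )
        if child.tag != "block":
            continue  # unknown elements become annotation candidates
        block = XmlBlock(
            identifier=_require_identifier(child, seen_blocks, "block"),
            donor_block=child.get("donor_block"),
            diagnosis_term=child.get("diagnosis_term"),
            extra=_extras(child, set()),
        )
        for sub in child:
            if not isinstance(sub.tag, str):
                continue
            if sub.tag == "block":
                raise DialectError("<block> may not contain <block>")
            if sub.tag == "core":
                block.cores.append(_parse_core(sub, seen_block_cores))
            elif sub.tag == "slide":
                slide = XmlSlide(
                    identifier=_require_identifier(sub, seen_slides, "slide"),
                    extra=_extras(sub, set()),
                )
                for leaf in sub:
                    if not isinstance(leaf.tag, str):
                        continue
                    if leaf.tag == "core":
                        slide.cores.append(
                            _parse_core(leaf, seen_slide_cores,
                                        scope=slide.identifier)
                        )
                    elif leaf.tag in ("block", "slide"):
                        raise DialectError(
                            f"<slide> may not contain <{leaf.tag}>"
                        )
                block.slides.append(slide)
        doc.blocks.append(block)
    return doc


def _annotation_predicate(name: str, vocab) -> Iri:
    if name in ("title", "creator"):
        return Iri(DC_NS + name)
    return Iri(vocab.iri(name))


def convert(xml: TmaXmlDocument, config: ConversionConfig) -> TmaGraph:
    """Transform a parsed TMA XML document into an instance graph.

    Every entity is minted an IRI via the policy (TMA and blocks) or as
    a document fragment (slides and cores); typing, annotation, and
    hierarchy statements are emitted in the configured direction, and a
    core on a slide is linked ``derived_from_core`` to the block core
    sharing its identifier.
    """
    vocab = build_schema()
    base = config.nsmap.base
    assert base is not None
    graph = TmaGraph(nsmap=config.nsmap)
    ns = vocab.namespace
    minted: dict[str, str] = {}

    def mint_external(schema_class: str, key: str) -> Iri:
        iri = config.policy.mint(schema_class, key)
        if str(iri) in minted:
            raise ConversionError(
                f"identifier collision: {key!r} mints {iri},"
                f" already used by {minted[str(iri)]!r}"
            )
        minted[str(iri)] = key
        return iri

    def fragment(key: str) -> Iri:
        iri = Iri(f"{base}#{percent_encode(key)}")
        if str(iri) in minted:
            raise ConversionError(
                f"identifier collision: {key!r} mints {iri},"
                f" already used by {minted[str(iri)]!r}"
            )
        minted[str(iri)] = key
        return iri

    def emit_type(iri: Iri, schema_class: str) -> None:
        graph.add(Triple(iri, RDF_TYPE, Iri(ns + schema_class)))

    def emit_annotation(iri: Iri, name: str, value: str) -> None:
        graph.add(Triple(iri, _annotation_predicate(name, vocab),
                         Literal(value)))

    def emit_edge(subject: Iri, top_down_prop: str, object: Iri) -> None:
        inverse = vocab.property(top_down_prop).inverse
        if config.direction in ("top_down", "both"):
            graph.add(Triple(subject, Iri(ns + top_down_prop), object))
        if config.direction in ("bottom_up", "both") and inverse is not None:
            graph.add(Triple(object, Iri(ns + inverse), subject))

    def emit_extras(iri: Iri, extra: dict[str, list[str]]) -> None:
        for name, values in extra.items():
            for v in values:
                emit_annotation(iri, name, v)

    tma_iri = mint_external("tma", xml.identifier)
    emit_type(tma_iri, "tma")
    if xml.title:
        emit_annotation(tma_iri, "title", xml.title)
    if xml.creator:
        emit_annotation(tma_iri, "creator", xml.creator)
    if xml.repository:
        emit_annotation(tma_iri, "repository", xml.repository)
    emit_extras(tma_iri, xml.extra)

    for block in xml.blocks:
        block_iri = mint_external("block", block.identifier)
        emit_type(block_iri, "block")
        emit_extras(block_iri, block.extra)
        emit_edge(tma_iri, "includes_block", block_iri)
        core_iris: dict[str, Iri] = {}
        for core in block.cores:
            core_iri = fragment(core.identifier)
            core_iris[core.identifier] = core_iri
            emit_type(core_iri, "core_in_block")
            emit_edge(block_iri, "block_includes_core", core_iri)
            if core.drill_site:
                emit_annotation(core_iri, "drill_site", core.drill_site)
            if core.location:
                emit_annotation(core_iri, "location", core.location)
            donor = core.donor_block or block.donor_block
            if donor:
                graph.add(Triple(core_iri, Iri(ns + "donor_block"), Iri(donor)))
            term = core.diagnosis_term or block.diagnosis_term
            if term:
                graph.add(Triple(core_iri, Iri(ns + "diagnosis"), Iri(term)))
            emit_extras(core_iri, core.extra)
        for slide in block.slides:
            slide_iri = fragment(slide.identifier)
            emit_type(slide_iri, "slide")
            emit_extras(slide_iri, slide.extra)
            emit_edge(block_iri, "includes_slide", slide_iri)
            for core in slide.cores:
                key = f"{slide.identifier}-{core.location or core.identifier}"
                section_iri = fragment(key)
                emit_type(section_iri, "core_on_slide")
                emit_edge(slide_iri, "slide_includes_core", section_iri)
                if core.location:
                    emit_annotation(section_iri, "location", core.location)
                if core.drill_site:
                    emit_annotation(section_iri, "drill_site", core.drill_site)
                if core.diagnosis_term:
                    graph.add(Triple(section_iri, Iri(ns + "diagnosis"),
                                     Iri(core.diagnosis_term)))
                if core.identifier in core_iris:
                    graph.add(Triple(section_iri, Iri(ns + "derived_from_core"),
                                     core_iris[core.identifier]))
                emit_extras(section_iri, core.extra)
    return graph
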