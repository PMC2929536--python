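"""The canonical worked example: a simplified one-core TMA.

An all-purpose tissue array (``tma/000001``) contains one recipient
block (``block/RP2008-325``); a slide (``#slide058``) was cut from the
block, which also holds one core (``#coreD4``) drilled from a donor
block in another repository; the section of that core on the slide
(``#slide058-D4``) sits at grid location D4 and carries a diagnosis
term from the NCI Thesaurus.  The TMA and block identifiers simulate
data files at their own addresses, while slide and cores live inside
the example document itself.

The example exercises every moving part: policy-minted absolute
identifiers, fragment identifiers under a document base, top-down
hierarchy edges, an external donor-block reference, literal
annotations, and an external-ontology term link.  Its projection is
exactly 18 statements.
"""

from __future__ import annotations

from .external_links import link_term
from .identifiers import Iri, NamespaceMap, UriPolicy
from .model import TmaModel, to_graph
from .rdf_io import TmaGraph
from .schema import DC_NS, TMA_NS

__all__ = [
    "EXAMPLE_BASE",
    "EXAMPLE_AUTHORITY",
    "example_nsmap",
    "example_policy",
    "example_model",
    "example_graph",
]

EXAMPLE_BASE = "http://www.the_url_here.org/tma_example1.rdf"
EXAMPLE_AUTHORITY = "www.institutionXYZ.org"
NCIT_PROSTATE = (
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma"
)


def example_nsmap() -> NamespaceMap:
    return NamespaceMap(prefixes={"tma": TMA_NS, "dc": DC_NS},
                        base=EXAMPLE_BASE)


def example_policy() -> UriPolicy:
    return UriPolicy(authority=EXAMPLE_AUTHORITY,
                     path_templates={"tma": ["tma"], "block": ["block"]})


def example_model() -> TmaModel:
    """Build the worked-example hierarchy through the typed model API."""
    policy = example_policy()
    tma_iri = policy.mint("tma", "000001")
    block_iri = policy.mint("block", "RP2008-325")
    donor_iri = policy.mint("block", "RP2007-228")
    slide_iri = Iri(EXAMPLE_BASE + "#slide058")
    core_iri = Iri(EXAMPLE_BASE + "#coreD4")
    section_iri = Iri(EXAMPLE_BASE + "#slide058-D4")

    m = TmaModel()
    m.add_node("tma", tma_iri, {
        DC_NS + "title": "All-Purpose Tissue Array",
        DC_NS + "creator": "Michael J. Becich",
    })
    m.add_node("block", block_iri)
    m.add_node("slide", slide_iri)
    m.add_node("core_in_block", core_iri, {
        "repository": "Generic Tissue Bank",
        "drill_site": "78,90",
    })
    m.add_node("core_on_slide", section_iri, {"location": "D4"})
    m.add_edge(tma_iri, "includes_block", block_iri)
    m.add_edge(block_iri, "includes_slide", slide_iri)
    m.add_edge(block_iri, "block_includes_core", core_iri)
    m.add_edge(slide_iri, "slide_includes_core", section_iri)
    m.add_edge(core_iri, "donor_block", donor_iri)
    m.add_edge(section_iri, "derived_from_core", core_iri)
    return m


def example_graph() -> TmaGraph:
    """The 18-statement worked-example graph, diagnosis link included."""
    graph = to_graph(example_model(), example_nsmap())
    return link_term(
        graph,
        Iri(EXAMPLE_BASE + "#coreD4"),
        "diagnosis",
        NCIT_PROSTATE,
        "#diagnosis1",
    )
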