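"""Linking TMA resources to external-ontology terms.

Diagnoses, clinical annotations, and assay results are deliberately
*not* modelled by the TMA vocabulary; instead a resource points at a
typed node whose class lives in an external ontology (an NCI Thesaurus
diagnosis class, an MGED-described microarray experiment, ...).  The
pattern is two statements::

    <core>       tma:diagnosis  <#diagnosis1> .
    <#diagnosis1>  rdf:type     <...Thesaurus.owl#Prostate_Carcinoma> .

The intermediate node may be a document fragment or a blank node.
External IRIs are opaque: they are never fetched or validated for
resolvability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .identifiers import Iri, NamespaceMap, expand
from .rdf_io import RDF_TYPE, BNode, Literal, TmaGraph, Triple
from .schema import SchemaVocabulary, build_schema

__all__ = ["LINK_PROPERTIES", "TermLink", "LinkError", "link_term",
           "link_experiment"]

#: Annotation properties usable as term-link predicates.
LINK_PROPERTIES = (
    "diagnosis",
    "clinical_annotation",
    "result",
    "assay",
    "protocol",
    "report_link",
)


class LinkError(ValueError):
    pass


@dataclass(frozen=True)
class TermLink:
    subject: Iri
    link_property: str
    node: "Iri | BNode"
    node_type: Iri | None = None


def _fresh_fragment(graph: TmaGraph, link_property: str) -> Iri:
    """Mint ``#<property><n>`` with the smallest unused counter."""
    base = graph.nsmap.base
    if base is None:
        raise LinkError("auto node ids need a document base IRI")
    used = {str(t.subject) for t in graph.triples} | {
        str(t.object) for t in graph.triples if not isinstance(t.object, Literal)
    }
    n = 1
    while f"{base}#{link_property}{n}" in used:
        n += 1
    return Iri(f"{base}#{link_property}{n}")


def link_term(graph: TmaGraph, subject: str, link_property: str,
              term_iri: str, node_id: "str | BNode | None" = None,
              nsmap: NamespaceMap | None = None) -> TmaGraph:
    """Attach an external-ontology term to ``subject``.

    Adds ``(subject, link_property, node)`` and ``(node, rdf:type,
    term_iri)``.  ``node_id`` may be a fragment/absolute IRI, a blank
    node, or None to auto-mint a ``#<property><counter>`` fragment.
    ``term_iri`` accepts ``prefix:local`` shorthand when ``nsmap`` (or
    the graph's map) binds the prefix.
    """
    if link_property not in LINK_PROPERTIES:
        raise LinkError(
            f"{link_property!r} is not a term-link property"
            f" (one of {', '.join(LINK_PROPERTIES)})"
        )
    subject = Iri(subject)
    if subject not in graph.subjects():
        raise LinkError(f"subject {subject} carries no statements in the graph")
    term = expand(term_iri, nsmap if nsmap is not None else graph.nsmap)
    if node_id is None:
        node = _fresh_fragment(graph, link_property)
    elif isinstance(node_id, BNode):
        node = node_id
    else:
        node = expand(node_id, nsmap if nsmap is not None else graph.nsmap)
    vocab = build_schema()
    out = graph.copy()
    out.add(Triple(subject, Iri(vocab.iri(link_property)), node))
    out.add(Triple(node, RDF_TYPE, term))
    return out


def link_experiment(graph: TmaGraph, core_on_slide: str, experiment_iri: str,
                    vocab: SchemaVocabulary | None = None,
                    link_property: str = "assay") -> TmaGraph:
    """Connect a core-on-slide to an externally described experiment.

    The subject must be typed ``core_on_slide`` in the graph — results
    attach to the physical section that was assayed, not to a block or
    slide.  The experiment IRI (e.g. an MGED-described microarray
    experiment) stays opaque.  The predicate defaults to the
    vocabulary's ``assay`` property and is configurable.
    """
    vocab = vocab if vocab is not None else build_schema()
    if link_property not in LINK_PROPERTIES:
        raise LinkError(f"{link_property!r} is not a term-link property")
    core_on_slide = Iri(core_on_slide)
    typing = Triple(core_on_slide, RDF_TYPE, Iri(vocab.iri("core_on_slide")))
    if typing not in graph.triples:
        raise LinkError(
            f"{core_on_slide} is not typed core_on_slide in the graph"
        )
    out = graph.copy()
    out.add(Triple(core_on_slide, Iri(vocab.iri(link_property)),
                   Iri(experiment_iri)))
    return out
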