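"""Reading, writing, and comparing TMA instance documents.

A :class:`TmaGraph` is a set of Subject-Predicate-Object statements
plus the namespace map used to abbreviate them.  Parsing and
serialization are backed by :mod:`rdflib`; on top of that this module
adds what instance-document tooling needs: a canonical triple ordering
for diffs, deterministic blank-node labels, graph isomorphism up to a
blank-node bijection, and normalization of the ``owl:Class``-as-typing
idiom that legacy documents carry (always emitted as ``rdf:type``).

Literals are kept as exact strings — a drill site ``"78,90"`` is never
reformatted or coerced to a number.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Iterator

from rdflib import Graph as RdflibGraph
from rdflib import BNode as RdflibBNode
from rdflib import Literal as RdflibLiteral
from rdflib import URIRef

from .identifiers import Iri, NamespaceMap

__all__ = [
    "RDF_TYPE",
    "OWL_CLASS",
    "Literal",
    "BNode",
    "Triple",
    "TmaGraph",
    "RdfIoError",
    "ParseError",
    "FormatError",
    "parse_document",
    "serialize",
    "canonical_triples",
    "canonical_bnode_labels",
    "graph_isomorphic",
    "normalize_typing",
]

RDF_TYPE = Iri("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
OWL_CLASS = Iri("http://www.w3.org/2002/07/owl#Class")

_FORMATS = {"rdf-xml": "xml", "turtle": "turtle", "ntriples": "nt"}


class RdfIoError(Exception):
    pass


class ParseError(RdfIoError):
    pass


class FormatError(RdfIoError, ValueError):
    pass


@dataclass(frozen=True)
class Literal:
    """A literal value with optional datatype IRI or language tag."""

    value: str
    datatype: str | None = None
    lang: str | None = None

    def __str__(self) -> str:
        return self.value


class BNode(str):
    """A document-scoped blank-node label (stored without ``_:``)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BNode({str.__repr__(self)})"


Term = "Iri | BNode | Literal"


@dataclass(frozen=True)
class Triple:
    subject: Iri | BNode
    predicate: Iri
    object: Iri | BNode | Literal

    def with_subject(self, subject: Iri | BNode) -> "Triple":
        return Triple(subject, self.predicate, self.object)

    def with_object(self, obj: "Iri | BNode | Literal") -> "Triple":
        return Triple(self.subject, self.predicate, obj)


def _term_key(term: object) -> tuple:
    # Sort blank nodes before IRIs before literals, each lexicographically.
    if isinstance(term, BNode):
        return (0, str(term))
    if isinstance(term, Literal):
        return (2, term.value, term.lang or "", term.datatype or "")
    return (1, str(term))


def triple_key(t: Triple) -> tuple:
    return (_term_key(t.subject), _term_key(t.predicate), _term_key(t.object))


class TmaGraph:
    """A set of triples with a namespace map (set semantics, no duplicates)."""

    def __init__(self, triples: Iterable[Triple] = (),
                 nsmap: NamespaceMap | None = None) -> None:
        self.triples: set[Triple] = set(triples)
        self.nsmap = nsmap if nsmap is not None else NamespaceMap()

    def add(self, triple: Triple) -> None:
        self.triples.add(triple)

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def copy(self) -> "TmaGraph":
        return TmaGraph(self.triples, self.nsmap)

    def subjects(self) -> set:
        return {t.subject for t in self.triples}

    def triples_with(self, subject=None, predicate=None, object=None) -> list[Triple]:
        return [
            t
            for t in self.triples
            if (subject is None or t.subject == subject)
            and (predicate is None or t.predicate == predicate)
            and (object is None or t.object == object)
        ]

    def value(self, subject, predicate):
        for t in self.triples:
            if t.subject == subject and t.predicate == predicate:
                return t.object
        return None


# -- rdflib bridge -----------------------------------------------------


def _to_rdflib_term(term):
    if isinstance(term, Literal):
        return RdflibLiteral(
            term.value,
            datatype=URIRef(term.datatype) if term.datatype else None,
            lang=term.lang,
        )
    if isinstance(term, BNode):
        return RdflibBNode(str(term))
    return URIRef(str(term))


def _from_rdflib_term(term):
    if isinstance(term, RdflibLiteral):
        return Literal(
            str(term),
            datatype=str(term.datatype) if term.datatype else None,
            lang=term.language,
        )
    if isinstance(term, RdflibBNode):
        return BNode(str(term))
    return Iri(str(term))


def to_rdflib(graph: TmaGraph, base: str | None = None) -> RdflibGraph:
    """Build an rdflib graph, inserting triples in canonical order."""
    g = RdflibGraph()
    for prefix, ns in sorted(graph.nsmap.prefixes.items()):
        if any(
            str(term).startswith(ns)
            for t in graph.triples
            for term in (t.subject, t.predicate, t.object)
            if not isinstance(term, Literal)
        ):
            g.bind(prefix, ns, override=True, replace=True)
    for t in canonical_triples(graph):
        g.add((_to_rdflib_term(t.subject), _to_rdflib_term(t.predicate),
               _to_rdflib_term(t.object)))
    return g


def from_rdflib(g: RdflibGraph, nsmap: NamespaceMap | None = None) -> TmaGraph:
    triples = {
        Triple(_from_rdflib_term(s), _from_rdflib_term(p), _from_rdflib_term(o))
        for s, p, o in g
    }
    if nsmap is None:
        prefixes = {
            prefix: str(ns)
            for prefix, ns in g.namespaces()
            if prefix and not prefix.startswith("default")
        }
        nsmap = NamespaceMap(prefixes=prefixes)
    return TmaGraph(triples, nsmap)


def parse_document(data: bytes | str, format: str = "rdf-xml",
                   nsmap: NamespaceMap | None = None,
                   base: str | None = None) -> TmaGraph:
    """Parse an instance document into a :class:`TmaGraph`.

    Shorthands are expanded to absolute IRIs by the parser; an in-document
    ``xml:base``/``@base`` is honored, and ``base`` supplies one for
    documents that rely on an out-of-band base.
    """
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}")
    g = RdflibGraph()
    try:
        g.parse(data=data, format=_FORMATS[format], publicID=base)
    except Exception as exc:  # rdflib raises parser-specific exceptions
        raise ParseError(f"cannot parse {format} document: {exc}") from exc
    graph = from_rdflib(g, nsmap)
    if base is None:
        base = _sniff_base(data, format)
    if base is not None and graph.nsmap.base is None:
        graph.nsmap = graph.nsmap.with_base(base)
    return graph


def _sniff_base(data: bytes | str, format: str) -> str | None:
    """Recover the declared document base (xml:base / @base), if any."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    if format == "rdf-xml":
        try:
            from lxml import etree

            root = etree.fromstring(data)
            return root.get("{http://www.w3.org/XML/1998/namespace}base")
        except Exception:
            return None
    if format == "turtle":
        for raw in data.decode("utf-8", "replace").splitlines():
            line = raw.strip()
            if line.lower().startswith(("@base", "base")) and "<" in line:
                return line[line.index("<") + 1 : line.index(">")]
    return None


def serialize(graph: TmaGraph, format: str = "rdf-xml") -> bytes:
    """Serialize deterministically: canonical triple order, sorted prefixes.

    When the namespace map carries a base IRI it is declared in the
    output (``xml:base`` / ``@base``), so the document re-parses without
    out-of-band information.
    """
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}")
    g = to_rdflib(graph)
    return g.serialize(format=_FORMATS[format], base=graph.nsmap.base,
                       encoding="utf-8")


# -- canonical ordering and isomorphism --------------------------------


def canonical_bnode_labels(graph: TmaGraph) -> dict[BNode, BNode]:
    """Deterministic relabeling of blank nodes.

    Each blank node is fingerprinted by the sorted set of its incident
    triples with itself replaced by a marker and other blank nodes
    anonymized; ties are broken by first occurrence in the sorted triple
    list.  Adequate for instance documents, which carry at most a
    handful of blank nodes (annotation bundles).
    """
    bnodes = {
        term
        for t in graph.triples
        for term in (t.subject, t.object)
        if isinstance(term, BNode)
    }
    if not bnodes:
        return {}

    def fingerprint(b: BNode) -> str:
        parts = []
        for t in graph.triples:
            if b not in (t.subject, t.object):
                continue

            def render(term):
                if term == b:
                    return "<self>"
                if isinstance(term, BNode):
                    return "<bnode>"
                if isinstance(term, Literal):
                    return f'"{term.value}"@{term.lang or ""}^^{term.datatype or ""}'
                return f"<{term}>"

            parts.append(f"{render(t.subject)} <{t.predicate}> {render(t.object)}")
        digest = hashlib.sha256("\n".join(sorted(parts)).encode("utf-8"))
        return digest.hexdigest()

    order: dict[BNode, int] = {}
    for t in sorted(graph.triples, key=triple_key):
        for term in (t.subject, t.object):
            if isinstance(term, BNode) and term not in order:
                order[term] = len(order)
    ranked = sorted(bnodes, key=lambda b: (fingerprint(b), order[b]))
    return {b: BNode(f"b{i}") for i, b in enumerate(ranked)}


def _relabel(graph: TmaGraph, mapping: dict[BNode, BNode]) -> TmaGraph:
    def m(term):
        return mapping.get(term, term) if isinstance(term, BNode) else term

    return TmaGraph(
        {Triple(m(t.subject), t.predicate, m(t.object)) for t in graph.triples},
        graph.nsmap,
    )


def canonical_triples(graph: TmaGraph) -> list[Triple]:
    """Triples sorted by (subject, predicate, object) over absolute IRIs,
    with blank nodes canonically relabeled first."""
    relabeled = _relabel(graph, canonical_bnode_labels(graph))
    return sorted(relabeled.triples, key=triple_key)


def graph_isomorphic(g1: TmaGraph, g2: TmaGraph) -> bool:
    """True iff some blank-node bijection maps g1's triples onto g2's.

    Exhaustive over blank-node permutations (grouped by fingerprint
    rank), which is fine at instance-document scale.
    """
    if len(g1.triples) != len(g2.triples):
        return False
    b1 = canonical_bnode_labels(g1)
    b2 = canonical_bnode_labels(g2)
    if len(b1) != len(b2):
        return False
    if _relabel(g1, b1).triples == _relabel(g2, b2).triples:
        return True
    # Canonical labels can mis-pair symmetric blank nodes; fall back to
    # brute force over the (few) blank nodes.
    nodes1 = sorted(b1, key=lambda b: str(b1[b]))
    nodes2 = sorted(b2, key=lambda b: str(b2[b]))
    ground2 = {t for t in g2.triples
               if not isinstance(t.subject, BNode)
               and not isinstance(t.object, BNode)}
    ground1 = {t for t in g1.triples
               if not isinstance(t.subject, BNode)
               and not isinstance(t.object, BNode)}
    if ground1 != ground2:
        return False
    for perm in permutations(nodes2):
        mapping = dict(zip(nodes1, perm))
        if _relabel(g1, mapping).triples == g2.triples:
            return True
    return False


def normalize_typing(graph: TmaGraph) -> tuple[TmaGraph, bool]:
    """Rewrite ``owl:Class`` used as a typing predicate to ``rdf:type``.

    Legacy documents state "instance X is of class C" with the predicate
    ``owl:Class``; the only well-formed reading is ``rdf:type``, which is
    what this library emits.  Returns the normalized graph and whether
    anything was rewritten.
    """
    changed = False
    triples = set()
    for t in graph.triples:
        if t.predicate == OWL_CLASS:
            triples.add(Triple(t.subject, RDF_TYPE, t.object))
            changed = True
        else:
            triples.add(t)
    return TmaGraph(triples, graph.nsmap), changed
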