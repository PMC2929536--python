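"""Typed in-memory representation of a TMA hierarchy.

A :class:`TmaModel` holds the nodes of the physical hierarchy — the
array itself, its recipient blocks, the slides cut from them, the cores
drilled into a block, and the core sections appearing on slides —
together with the object-property edges that relate them and open
annotation maps on each node.  ``to_graph`` / ``from_graph`` project
the model to and from its triple representation losslessly.

Edges are checked against the vocabulary's domain/range on insertion,
with one deliberate exception: an edge may point at a resource that is
not part of the model (a donor block in another repository, a parent
TMA described in a different document).  Such external references are
stored as opaque IRIs and never resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .identifiers import Iri, NamespaceMap
from .rdf_io import RDF_TYPE, BNode, Literal, TmaGraph, Triple, triple_key
from .schema import DC_NS, SchemaVocabulary, build_schema

__all__ = [
    "TmaNode",
    "TmaModel",
    "ModelError",
    "GraphProjectionError",
    "to_graph",
    "from_graph",
]

AnnotationValue = "Literal | Iri | str"


class ModelError(ValueError):
    """A model construction rule was violated."""


class GraphProjectionError(ModelError):
    """A graph could not be projected onto the typed model."""


def _as_value(value) -> Literal | Iri:
    """Plain strings are literals; Iri marks a resource value."""
    if isinstance(value, (Literal, Iri, BNode)):
        return value
    if isinstance(value, str):
        return Literal(value)
    raise ModelError(f"unsupported annotation value {value!r}")


def _value_key(v) -> tuple:
    if isinstance(v, Literal):
        return (1, v.value, v.lang or "", v.datatype or "")
    return (0, str(v))


@dataclass
class TmaNode:
    """One resource of the hierarchy with its annotation map.

    ``annotations`` maps a property token — either one of the fifteen
    vocabulary annotation properties (``location``, ``drill_site``,
    ``repository``, ...) or an absolute IRI of an external annotation
    property such as Dublin Core ``title`` — to the list of its values.
    """

    iri: Iri
    schema_class: str
    annotations: dict[str, list] = field(default_factory=dict)

    def add_annotation(self, prop: str, value) -> None:
        self.annotations.setdefault(prop, []).append(_as_value(value))
        self.annotations[prop].sort(key=_value_key)

    def _canonical(self) -> tuple:
        anns = tuple(
            (k, tuple(sorted(map(_value_key, vs))))
            for k, vs in sorted(self.annotations.items())
        )
        return (str(self.iri), self.schema_class, anns)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TmaNode):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())


class TmaModel:
    """A TMA hierarchy: typed nodes plus object-property edges."""

    def __init__(self, vocab: SchemaVocabulary | None = None) -> None:
        self.vocab = vocab if vocab is not None else build_schema()
        self.nodes: dict[Iri, TmaNode] = {}
        self.edges: set[tuple[Iri, str, Iri]] = set()
        # Statements about auxiliary resources (diagnosis term nodes,
        # annotation bundles) that are not hierarchy nodes themselves.
        self.extra_triples: set[Triple] = set()

    # -- views ---------------------------------------------------------

    def nodes_of(self, schema_class: str) -> list[TmaNode]:
        return sorted(
            (n for n in self.nodes.values() if n.schema_class == schema_class),
            key=lambda n: str(n.iri),
        )

    @property
    def arrays(self) -> list[TmaNode]:
        return self.nodes_of("tma")

    @property
    def blocks(self) -> list[TmaNode]:
        return self.nodes_of("block")

    @property
    def slides(self) -> list[TmaNode]:
        return self.nodes_of("slide")

    @property
    def cores_in_block(self) -> list[TmaNode]:
        return self.nodes_of("core_in_block")

    @property
    def cores_on_slide(self) -> list[TmaNode]:
        return self.nodes_of("core_on_slide")

    # -- construction --------------------------------------------------

    def add_node(self, schema_class: str, iri: str,
                 annotations: dict | None = None) -> TmaNode:
        """Register a node; the class must be concrete and the IRI fresh."""
        if schema_class not in self.vocab.class_names:
            raise ModelError(f"unknown schema class {schema_class!r}")
        if schema_class in self.vocab.abstract_class_names:
            raise ModelError(
                f"cannot instantiate abstract class {schema_class!r}"
            )
        iri = Iri(iri)
        if iri in self.nodes:
            raise ModelError(f"duplicate node IRI {iri}")
        node = TmaNode(iri, schema_class)
        for prop, values in (annotations or {}).items():
            if not isinstance(values, (list, tuple)):
                values = [values]
            for v in values:
                node.add_annotation(prop, v)
        self.nodes[iri] = node
        return node

    def add_edge(self, subject: str, property_name: str,
                 object: str) -> tuple[Iri, str, Iri]:
        """Add an object-property edge, enforcing domain/range.

        The range is only enforced when the object is itself a node of
        the model; an absent object is an external reference and is
        accepted as-is.
        """
        subject, object = Iri(subject), Iri(object)
        prop = self.vocab.property(property_name)
        if prop.kind != "object":
            raise ModelError(f"{property_name!r} is not an object property")
        if subject not in self.nodes:
            raise ModelError(f"edge subject {subject} is not in the model")
        subject_class = self.nodes[subject].schema_class
        if prop.domain != "any" and subject_class != prop.domain:
            raise ModelError(
                f"domain violation: {property_name} expects a {prop.domain}"
                f" subject, got {subject_class}"
            )
        if object in self.nodes and prop.range not in ("external",
                                                       "literal-or-resource"):
            object_class = self.nodes[object].schema_class
            if object_class != prop.range:
                raise ModelError(
                    f"range violation: {property_name} expects a {prop.range}"
                    f" object, got {object_class}"
                )
        edge = (subject, property_name, object)
        self.edges.add(edge)
        return edge

    # -- comparison ----------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, TmaModel):
            return NotImplemented
        return (
            set(self.nodes.values()) == set(other.nodes.values())
            and self.edges == other.edges
            and self.extra_triples == other.extra_triples
        )

    def __hash__(self) -> int:  # pragma: no cover - models are mutable
        raise TypeError("TmaModel is not hashable")

    def triple_count(self) -> int:
        """Number of instance triples the projection will produce."""
        n_annotations = sum(
            len(vs) for node in self.nodes.values()
            for vs in node.annotations.values()
        )
        return (len(self.nodes) + n_annotations + len(self.edges)
                + len(self.extra_triples))


def _annotation_iri(prop: str, vocab: SchemaVocabulary) -> Iri:
    if prop.startswith("http://") or prop.startswith("https://"):
        return Iri(prop)
    return Iri(vocab.iri(prop))


def to_graph(model: TmaModel, nsmap: NamespaceMap | None = None) -> TmaGraph:
    """Project the model to triples.

    One ``rdf:type`` triple per node, one triple per annotation value,
    one per edge, plus the model's auxiliary statements.  No inverse
    triples are added; materialization is a separate, explicit step.
    """
    vocab = model.vocab
    if nsmap is None:
        nsmap = NamespaceMap(prefixes={"tma": vocab.namespace, "dc": DC_NS})
    graph = TmaGraph(nsmap=nsmap)
    for node in model.nodes.values():
        graph.add(Triple(node.iri, RDF_TYPE, Iri(vocab.iri(node.schema_class))))
        for prop, values in node.annotations.items():
            pred = _annotation_iri(prop, vocab)
            for v in values:
                graph.add(Triple(node.iri, pred, v))
    for subject, prop, object in model.edges:
        graph.add(Triple(subject, Iri(vocab.iri(prop)), object))
    for t in model.extra_triples:
        graph.add(t)
    return graph


def from_graph(graph: TmaGraph, vocab: SchemaVocabulary | None = None) -> TmaModel:
    """Rebuild a typed model from an instance graph (inverse of
    :func:`to_graph`).

    Nodes come from ``rdf:type`` triples whose object is a concrete
    vocabulary class; object-property triples become edges; everything
    else about a node becomes an annotation (vocabulary annotation
    properties under their token, foreign predicates under their full
    IRI).  Statements about resources that are not hierarchy nodes are
    preserved verbatim so the projection is lossless.
    """
    vocab = vocab if vocab is not None else build_schema()
    model = TmaModel(vocab)
    ns = vocab.namespace

    def vocab_local(iri: str) -> str | None:
        return iri[len(ns):] if str(iri).startswith(ns) else None

    typed: dict = {}
    # Sorted iteration keeps "first concrete type wins" deterministic.
    for t in sorted(graph.triples, key=triple_key):
        if t.predicate == RDF_TYPE and not isinstance(t.object, Literal):
            local = vocab_local(str(t.object))
            if local in vocab.class_names and t.subject not in typed:
                typed[t.subject] = local
    for subject, local in typed.items():
        if local in vocab.abstract_class_names:
            raise GraphProjectionError(
                f"{subject} is typed with abstract class {local!r}"
            )
        model.add_node(local, subject)

    edge_triples: list[Triple] = []
    for t in sorted(graph.triples, key=triple_key):
        if t.predicate == RDF_TYPE and t.subject in typed:
            obj_local = vocab_local(str(t.object))
            if obj_local == typed[t.subject]:
                continue  # the typing triple itself
        local = vocab_local(str(t.predicate))
        if local is not None and vocab.has_property(local):
            prop = vocab.property(local)
            if prop.kind == "object":
                if t.subject not in typed:
                    raise GraphProjectionError(
                        f"subject {t.subject} of vocabulary property "
                        f"{local!r} is not typed"
                    )
                edge_triples.append(t)
                continue
            if t.subject in typed:
                model.nodes[t.subject].add_annotation(local, t.object)
                continue
            raise GraphProjectionError(
                f"subject {t.subject} of vocabulary property {local!r}"
                " is not typed"
            )
        if t.subject in typed:
            model.nodes[t.subject].add_annotation(str(t.predicate), t.object)
        else:
            model.extra_triples.add(t)
    for t in edge_triples:
        local = vocab_local(str(t.predicate))
        assert local is not None
        if isinstance(t.object, Literal):
            raise GraphProjectionError(
                f"object property {local!r} used with literal {t.object.value!r}"
            )
        try:
            model.add_edge(t.subject, local, Iri(str(t.object)))
        except ModelError as exc:
            raise GraphProjectionError(str(exc)) from exc
    return model
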