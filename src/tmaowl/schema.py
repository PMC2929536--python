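"""The TMA minimal vocabulary.

Seven classes describe the physical hierarchy of a tissue microarray:
two abstract parents (``repository_product`` for the dispensable
physical artifacts, ``experimental_component`` for the experimental
units) and five concrete classes (``tma``, ``block``, ``slide``,
``core_in_block``, ``core_on_slide``).  Ten object properties wire the
hierarchy together; four of them come in inverse pairs, one "top-down"
member pointing from container to part (``includes_block``,
``includes_slide``, ``block_includes_core``, ``slide_includes_core``)
and one "bottom-up" member pointing from part to parent
(``included_in_tma``, ``cut_from_block``, ``included_in_block``,
``affixed_to_slide``).  Fifteen annotation-style properties carry
descriptive values (drill site, grid location, repository name,
diagnosis, assay results, ...); they accept either a literal or a
resource, since in practice a diagnosis may be a plain string or a
pointer to an external ontology term.

:func:`build_schema` returns the vocabulary as data;
:func:`emit_schema_document` serializes it as an OWL schema document
(class declarations, subclass axioms, domain/range, ``owl:inverseOf``),
and :func:`rebuild_schema` reads such a document back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal as TypingLiteral

from rdflib import Graph, Namespace, RDF, RDFS, OWL, URIRef

__all__ = [
    "TMA_NS",
    "DC_NS",
    "SchemaClass",
    "SchemaProperty",
    "SchemaVocabulary",
    "SchemaError",
    "UnknownPropertyError",
    "SchemaFormatError",
    "build_schema",
    "emit_schema_document",
    "rebuild_schema",
    "inverse_of",
]

#: Default namespace of the vocabulary, as expanded by the published
#: shorthand table (``tma:block`` -> ``...tma-minimal#block``).
TMA_NS = "http://bioontology.org/ontologies/tma-minimal#"

#: Dublin Core namespace as this vocabulary's documents expand it
#: (``dc:title`` -> ``...1.1#title``).
DC_NS = "http://purl.org/dc/elements/1.1#"

ABSTRACT_CLASSES = ("repository_product", "experimental_component")
CONCRETE_CLASSES = ("tma", "block", "slide", "core_in_block", "core_on_slide")

#: (domain, range) pairs in which the domain *contains* the range in the
#: physical hierarchy.  A paired object property is "top-down" exactly
#: when its (domain, range) is a containment pair; this is what lets a
#: re-parsed schema document recover property directions.
CONTAINMENT = frozenset(
    [
        ("tma", "block"),
        ("block", "slide"),
        ("block", "core_in_block"),
        ("slide", "core_on_slide"),
    ]
)


class SchemaError(ValueError):
    """Base class for vocabulary failures."""


class UnknownPropertyError(SchemaError, KeyError):
    """A property token is not part of the vocabulary."""


class SchemaFormatError(SchemaError):
    """Unsupported serialization format for the schema document."""


@dataclass(frozen=True)
class SchemaClass:
    local_name: str
    parent: str | None = None
    abstract: bool = False


@dataclass(frozen=True)
class SchemaProperty:
    local_name: str
    kind: TypingLiteral["object", "annotation"]
    domain: str = "any"
    range: str = "literal-or-resource"
    inverse: str | None = None
    direction: TypingLiteral["top_down", "bottom_up", "none"] = "none"


@dataclass(frozen=True)
class SchemaVocabulary:
    classes: frozenset[SchemaClass]
    properties: frozenset[SchemaProperty]
    namespace: str = TMA_NS

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", frozenset(self.classes))
        object.__setattr__(self, "properties", frozenset(self.properties))
        names = [c.local_name for c in self.classes]
        if len(names) != len(set(names)):
            raise SchemaError("duplicate class names in vocabulary")
        for p in self.properties:
            if p.inverse is not None:
                q = self.property(p.inverse)
                if q.inverse != p.local_name:
                    raise SchemaError(
                        f"inverse pairing of {p.local_name} is not symmetric"
                    )
                if (p.domain, p.range) != (q.range, q.domain):
                    raise SchemaError(
                        f"domain/range of {p.local_name} and {q.local_name}"
                        " are not dual"
                    )

    # -- lookups -------------------------------------------------------

    def cls(self, local_name: str) -> SchemaClass:
        for c in self.classes:
            if c.local_name == local_name:
                return c
        raise SchemaError(f"unknown class {local_name!r}")

    def has_property(self, local_name: str) -> bool:
        return any(p.local_name == local_name for p in self.properties)

    @property
    def class_names(self) -> frozenset[str]:
        return frozenset(c.local_name for c in self.classes)

    @property
    def concrete_class_names(self) -> frozenset[str]:
        return frozenset(c.local_name for c in self.classes if not c.abstract)

    @property
    def abstract_class_names(self) -> frozenset[str]:
        return frozenset(c.local_name for c in self.classes if c.abstract)

    @property
    def object_properties(self) -> frozenset[SchemaProperty]:
        return frozenset(p for p in self.properties if p.kind == "object")

    @property
    def annotation_properties(self) -> frozenset[SchemaProperty]:
        return frozenset(p for p in self.properties if p.kind == "annotation")

    def iri(self, local_name: str) -> str:
        return self.namespace + local_name

    # Defined last: the name shadows the builtin inside the class body.
    def property(self, local_name: str) -> SchemaProperty:
        for p in self.properties:
            if p.local_name == local_name:
                return p
        raise UnknownPropertyError(local_name)

    def with_parent_override(self, assignments: dict[str, str]) -> "SchemaVocabulary":
        """Return a copy with some concrete classes re-parented.

        The true placement of the concrete classes under the two
        abstract parents is a published-schema detail this library
        cannot verify, so it is configurable.
        """
        classes = []
        for c in self.classes:
            if c.local_name in assignments:
                parent = assignments[c.local_name]
                if parent not in ABSTRACT_CLASSES:
                    raise SchemaError(f"{parent!r} is not an abstract parent")
                classes.append(replace(c, parent=parent))
            else:
                classes.append(c)
        return SchemaVocabulary(frozenset(classes), self.properties, self.namespace)


def _object_property(name: str, domain: str, rng: str, inverse: str | None,
                     direction: str) -> SchemaProperty:
    return SchemaProperty(name, "object", domain, rng, inverse, direction)  # type: ignore[arg-type]


_CLASSES = (
    SchemaClass("repository_product", None, abstract=True),
    SchemaClass("experimental_component", None, abstract=True),
    SchemaClass("tma", "repository_product"),
    SchemaClass("block", "repository_product"),
    SchemaClass("slide", "repository_product"),
    SchemaClass("core_in_block", "experimental_component"),
    SchemaClass("core_on_slide", "experimental_component"),
)

_OBJECT_PROPERTIES = (
    _object_property("includes_block", "tma", "block", "included_in_tma", "top_down"),
    _object_property("included_in_tma", "block", "tma", "includes_block", "bottom_up"),
    _object_property("includes_slide", "block", "slide", "cut_from_block", "top_down"),
    _object_property("cut_from_block", "slide", "block", "includes_slide", "bottom_up"),
    _object_property("block_includes_core", "block", "core_in_block",
                     "included_in_block", "top_down"),
    _object_property("included_in_block", "core_in_block", "block",
                     "block_includes_core", "bottom_up"),
    _object_property("slide_includes_core", "slide", "core_on_slide",
                     "affixed_to_slide", "top_down"),
    _object_property("affixed_to_slide", "core_on_slide", "slide",
                     "slide_includes_core", "bottom_up"),
    _object_property("derived_from_core", "core_on_slide", "core_in_block",
                     None, "none"),
    _object_property("donor_block", "core_in_block", "external", None, "none"),
)

ANNOTATION_PROPERTY_NAMES = (
    "status",
    "level",
    "size",
    "thickness",
    "core_spacing",
    "location",
    "diagnosis",
    "clinical_annotation",
    "drill_site",
    "protocol",
    "report_link",
    "control",
    "result",
    "repository",
    "assay",
)


def build_schema(namespace: str = TMA_NS) -> SchemaVocabulary:
    """Return the complete TMA minimal vocabulary."""
    props = list(_OBJECT_PROPERTIES) + [
        SchemaProperty(name, "annotation") for name in ANNOTATION_PROPERTY_NAMES
    ]
    return SchemaVocabulary(frozenset(_CLASSES), frozenset(props), namespace)


def inverse_of(vocab: SchemaVocabulary, property_name: str) -> str | None:
    """The paired inverse of ``property_name``, or None when unpaired."""
    return vocab.property(property_name).inverse


_FORMATS = {"rdf-xml": "xml", "turtle": "turtle"}


def emit_schema_document(vocab: SchemaVocabulary, format: str = "rdf-xml") -> bytes:
    """Serialize the vocabulary as an OWL schema document.

    Declares each class (with a subclass axiom to its abstract parent),
    each object property with domain, range, and an ``owl:inverseOf``
    axiom where paired, and each annotation property.  ``external``
    ranges and ``any`` domains are expressed by omission — they carry no
    axiom.  :func:`rebuild_schema` inverts this exactly.
    """
    if format not in _FORMATS:
        raise SchemaFormatError(f"unsupported schema format {format!r}")
    ns = Namespace(vocab.namespace)
    g = Graph()
    g.bind("tma", ns)
    g.bind("owl", OWL)
    ontology = URIRef(vocab.namespace.rstrip("#"))
    g.add((ontology, RDF.type, OWL.Ontology))
    for c in sorted(vocab.classes, key=lambda c: c.local_name):
        g.add((ns[c.local_name], RDF.type, OWL.Class))
        if c.parent is not None:
            g.add((ns[c.local_name], RDFS.subClassOf, ns[c.parent]))
    for p in sorted(vocab.properties, key=lambda p: p.local_name):
        iri = ns[p.local_name]
        if p.kind == "object":
            g.add((iri, RDF.type, OWL.ObjectProperty))
            if p.domain != "any":
                g.add((iri, RDFS.domain, ns[p.domain]))
            if p.range not in ("external", "literal-or-resource"):
                g.add((iri, RDFS.range, ns[p.range]))
            if p.inverse is not None:
                g.add((iri, OWL.inverseOf, ns[p.inverse]))
        else:
            g.add((iri, RDF.type, OWL.AnnotationProperty))
    return g.serialize(format=_FORMATS[format], encoding="utf-8")


def rebuild_schema(document: bytes, format: str = "rdf-xml",
                   namespace: str = TMA_NS) -> SchemaVocabulary:
    """Parse an emitted schema document back into a vocabulary.

    Inverse of :func:`emit_schema_document`: a class with no subclass
    axiom is abstract; an object property with no range axiom has range
    ``external``; a paired property is top-down exactly when its
    (domain, range) is a containment pair of the physical hierarchy.
    """
    if format not in _FORMATS:
        raise SchemaFormatError(f"unsupported schema format {format!r}")
    g = Graph()
    g.parse(data=document, format=_FORMATS[format])

    def local(term: URIRef) -> str:
        if not str(term).startswith(namespace):
            raise SchemaError(f"{term} is outside the vocabulary namespace")
        return str(term)[len(namespace):]

    classes = []
    for s in g.subjects(RDF.type, OWL.Class):
        name = local(s)
        parent = g.value(s, RDFS.subClassOf)
        classes.append(
            SchemaClass(name, local(parent) if parent is not None else None,
                        abstract=parent is None)
        )
    props: list[SchemaProperty] = []
    inverses: dict[str, str] = {}
    for s, _, o in g.triples((None, OWL.inverseOf, None)):
        inverses[local(s)] = local(o)
        inverses[local(o)] = local(s)
    for s in g.subjects(RDF.type, OWL.ObjectProperty):
        name = local(s)
        domain = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        inverse = inverses.get(name)
        domain_name = local(domain) if domain is not None else "any"
        range_name = local(rng) if rng is not None else "external"
        direction = "none"
        if inverse is not None:
            direction = (
                "top_down" if (domain_name, range_name) in CONTAINMENT else "bottom_up"
            )
        props.append(
            SchemaProperty(name, "object", domain_name, range_name, inverse, direction)  # type: ignore[arg-type]
        )
    for s in g.subjects(RDF.type, OWL.AnnotationProperty):
        props.append(SchemaProperty(local(s), "annotation"))
    return SchemaVocabulary(frozenset(classes), frozenset(props), namespace)
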