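"""Instance-graph validation and inverse-property materialization.

Validation checks an instance graph against the vocabulary and reports
findings rather than raising: structural violations (untyped subjects,
domain/range mismatches, dangling fragment references, instantiated
abstract classes) are errors; stylistic issues (legacy typing
predicate, unusual location or drill-site shapes, external references)
are warnings.  External references — donor blocks, diagnosis terms,
experiment files in other documents — are never errors: unresolved
identifiers are how TMA documents cross-link by design.

The vocabulary's four inverse pairs support one inference:
:func:`materialize_inverses` adds the mirror statement of every paired
edge, so a document written "top-down" (container to part) entails its
"bottom-up" reading and vice versa.  :func:`strip_inverses` removes one
direction again, e.g. to publish a whole-hierarchy document with only
top-down edges.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Literal as TypingLiteral

from .identifiers import Iri, is_internal
from .rdf_io import (
    OWL_CLASS,
    RDF_TYPE,
    BNode,
    Literal,
    TmaGraph,
    Triple,
    normalize_typing,
    triple_key,
)
from .schema import SchemaVocabulary, build_schema

__all__ = [
    "RULES",
    "ValidationFinding",
    "ValidationReport",
    "validate",
    "materialize_inverses",
    "strip_inverses",
    "InverseConsistencyError",
]

#: Registry of validation rules.  E-rules are errors, W-rules warnings.
RULES: dict[str, str] = {
    "E1": "subject of a vocabulary object property is not typed with a concrete class",
    "E2": "object-property domain violation",
    "E3": "object-property range violation (internal, typed object)",
    "E4": "dangling internal fragment reference",
    "E5": "resource typed with an abstract class",
    "W1": "legacy owl:Class used as typing predicate (normalized to rdf:type)",
    "W2": "location value is not in letter+digits grid form",
    "W3": "drill_site value is not in 'integer,integer' form",
    "W4": "annotation property used in an unconventional way",
    "W5": "external reference (informational)",
}

_GRID_RE = re.compile(r"^[A-Z]+[0-9]+$")
_DRILL_RE = re.compile(r"^[0-9]+,[0-9]+$")


class InverseConsistencyError(ValueError):
    """A graph holds one direction of a pair inconsistently."""


@dataclass(frozen=True)
class ValidationFinding:
    rule_id: str
    severity: TypingLiteral["error", "warning"]
    node: str
    message: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULES:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    def by_rule(self, rule_id: str) -> list[ValidationFinding]:
        return [f for f in self.findings if f.rule_id == rule_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "valid": self.valid,
                "findings": [
                    {
                        "rule_id": f.rule_id,
                        "severity": f.severity,
                        "node": str(f.node),
                        "message": f.message,
                    }
                    for f in self.findings
                ],
            },
            indent=2,
        )

    def render_text(self) -> str:
        if not self.findings:
            return "valid: no findings\n"
        lines = [f"valid: {str(self.valid).lower()}"]
        for f in self.findings:
            lines.append(f"[{f.rule_id}:{f.severity}] {f.node}: {f.message}")
        return "\n".join(lines) + "\n"


def validate(graph: TmaGraph, vocab: SchemaVocabulary | None = None,
             base: str | None = None) -> ValidationReport:
    """Check an instance graph against the vocabulary.

    Never mutates ``graph`` and never raises on content: every problem
    becomes a finding.  ``base`` defaults to the graph's namespace-map
    base and scopes the internal/external distinction.
    """
    vocab = vocab if vocab is not None else build_schema()
    if base is None:
        base = graph.nsmap.base
    report = ValidationReport()
    add = report.findings.append

    normalized, had_legacy_typing = normalize_typing(graph)
    if had_legacy_typing:
        add(ValidationFinding(
            "W1", "warning", "-",
            "owl:Class used as typing predicate; read as rdf:type",
        ))

    ns = vocab.namespace

    def vocab_local(iri) -> str | None:
        s = str(iri)
        return s[len(ns):] if s.startswith(ns) else None

    triples = sorted(normalized.triples, key=triple_key)

    # Typing map: first concrete vocabulary type wins.
    types: dict[object, str] = {}
    for t in triples:
        if t.predicate != RDF_TYPE or isinstance(t.object, Literal):
            continue
        local = vocab_local(t.object)
        if local is None or local not in vocab.class_names:
            continue
        if local in vocab.abstract_class_names:
            add(ValidationFinding(
                "E5", "error", str(t.subject),
                f"typed with abstract class {local!r}",
            ))
            continue
        if t.subject in types:
            add(ValidationFinding(
                "W4", "warning", str(t.subject),
                f"multiple vocabulary types; keeping {types[t.subject]!r}",
            ))
            continue
        types[t.subject] = local

    subjects = {t.subject for t in triples}
    mentioned_internal: set[str] = set()

    for t in triples:
        local = vocab_local(t.predicate)
        prop = None
        if local is not None and vocab.has_property(local):
            prop = vocab.property(local)

        if prop is not None and prop.kind == "object":
            subject_type = types.get(t.subject)
            if subject_type is None:
                add(ValidationFinding(
                    "E1", "error", str(t.subject),
                    f"subject of {local!r} has no concrete vocabulary type",
                ))
            elif prop.domain != "any" and subject_type != prop.domain:
                add(ValidationFinding(
                    "E2", "error", str(t.subject),
                    f"{local!r} expects a {prop.domain} subject,"
                    f" found {subject_type}",
                ))
            if isinstance(t.object, Literal):
                add(ValidationFinding(
                    "E3", "error", str(t.subject),
                    f"object property {local!r} used with a literal",
                ))
            else:
                object_type = types.get(t.object)
                internal = (
                    isinstance(t.object, BNode)
                    or (base is not None and is_internal(str(t.object), base))
                )
                if (
                    object_type is not None
                    and prop.range not in ("external", "literal-or-resource")
                    and internal
                    and object_type != prop.range
                ):
                    add(ValidationFinding(
                        "E3", "error", str(t.object),
                        f"{local!r} expects a {prop.range} object,"
                        f" found {object_type}",
                    ))
                if internal and not isinstance(t.object, BNode):
                    if t.object not in subjects:
                        mentioned_internal.add(str(t.object))
                if not internal and not isinstance(t.object, BNode):
                    add(ValidationFinding(
                        "W5", "warning", str(t.object),
                        f"external reference via {local!r} (not resolved)",
                    ))

        elif prop is not None:  # annotation property
            if local == "location" and isinstance(t.object, Literal):
                if not _GRID_RE.match(t.object.value):
                    add(ValidationFinding(
                        "W2", "warning", str(t.subject),
                        f"location {t.object.value!r} is not grid-shaped"
                        " (expected e.g. 'D4')",
                    ))
            if local == "drill_site" and isinstance(t.object, Literal):
                if not _DRILL_RE.match(t.object.value):
                    add(ValidationFinding(
                        "W3", "warning", str(t.subject),
                        f"drill_site {t.object.value!r} is not 'x,y'"
                        " (expected e.g. '78,90')",
                    ))
            if local in ("location", "drill_site", "repository") and not isinstance(
                t.object, Literal
            ):
                add(ValidationFinding(
                    "W4", "warning", str(t.subject),
                    f"{local!r} conventionally carries a literal value",
                ))
            if not isinstance(t.object, (Literal, BNode)):
                internal = base is not None and is_internal(str(t.object), base)
                if internal and t.object not in subjects:
                    mentioned_internal.add(str(t.object))
                elif not internal:
                    add(ValidationFinding(
                        "W5", "warning", str(t.object),
                        f"external reference via {local!r} (not resolved)",
                    ))

    for iri in sorted(mentioned_internal):
        add(ValidationFinding(
            "E4", "error", iri,
            "internal fragment is referenced but carries no statements",
        ))

    return report


def _paired(vocab: SchemaVocabulary) -> dict[str, str]:
    return {
        p.local_name: p.inverse
        for p in vocab.object_properties
        if p.inverse is not None
    }


def materialize_inverses(graph: TmaGraph,
                         vocab: SchemaVocabulary | None = None) -> TmaGraph:
    """Add the mirror statement of every paired object-property triple.

    For each ``(a, p, b)`` with paired inverse ``q``, the result also
    contains ``(b, q, a)``.  Idempotent; never removes anything.
    """
    vocab = vocab if vocab is not None else build_schema()
    pairs = _paired(vocab)
    ns = vocab.namespace
    out = graph.copy()
    for t in graph.triples:
        local = str(t.predicate)[len(ns):] if str(t.predicate).startswith(ns) else None
        if local in pairs and not isinstance(t.object, Literal):
            out.add(Triple(t.object, Iri(ns + pairs[local]), t.subject))
    return out


def strip_inverses(graph: TmaGraph, vocab: SchemaVocabulary | None = None,
                   keep: TypingLiteral["top_down", "bottom_up"] = "top_down",
                   ) -> TmaGraph:
    """Keep only one direction of each inverse pair.

    Requires an inverse-consistent (materialized) input so no
    information is lost: :func:`materialize_inverses` recovers the full
    graph exactly.
    """
    if keep not in ("top_down", "bottom_up"):
        raise ValueError(f"keep must be top_down or bottom_up, got {keep!r}")
    vocab = vocab if vocab is not None else build_schema()
    ns = vocab.namespace
    pairs = _paired(vocab)
    directions = {p.local_name: p.direction for p in vocab.object_properties}
    for t in graph.triples:
        local = str(t.predicate)[len(ns):] if str(t.predicate).startswith(ns) else None
        if local in pairs and not isinstance(t.object, Literal):
            mirror = Triple(t.object, Iri(ns + pairs[local]), t.subject)
            if mirror not in graph.triples:
                raise InverseConsistencyError(
                    f"({t.subject}, {local}, {t.object}) has no mirror"
                    " statement; materialize before stripping"
                )
    kept = set()
    for t in graph.triples:
        local = str(t.predicate)[len(ns):] if str(t.predicate).startswith(ns) else None
        if local in pairs and directions.get(local) != keep:
            continue
        kept.add(t)
    return TmaGraph(kept, graph.nsmap)
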