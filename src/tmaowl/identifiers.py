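"""Resource identifiers: minting, expansion, and compaction.

Tissue-microarray resources are published as Linked Data: every TMA,
block, slide, and core gets a stable HTTP identifier under the
publisher's own authority, keyed by the identifier that is meaningful in
the publisher's domain (an accession number such as ``RP2008-325``, a
bank identifier, ...).  Instance documents abbreviate identifiers either
as ``prefix:local`` shorthands against a namespace map, or as
``#fragment`` extensions of the document base.

This module owns those three concerns: :func:`mint_uri` builds
identifiers from a :class:`UriPolicy`, :func:`expand` /
:func:`compact` translate between shorthands and absolute IRIs, and
:func:`is_internal` classifies an identifier as living inside or
outside a given document.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Iri",
    "NamespaceMap",
    "UriPolicy",
    "IdentifierError",
    "MintingError",
    "ExpansionError",
    "percent_encode",
    "mint_uri",
    "expand",
    "compact",
    "is_internal",
]

# RFC 3986 unreserved characters: left untouched by percent-encoding.
_UNRESERVED = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-._~"
)
_HEX = frozenset("0123456789abcdefABCDEF")


class Iri(str):
    """An absolute IRI (or blank-node label elsewhere), as a plain string.

    Subclassing :class:`str` lets annotation and triple values
    distinguish "this string names a resource" from "this string is a
    literal" without a parallel wrapper type.
    """

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Iri({str.__repr__(self)})"


class IdentifierError(ValueError):
    """Base class for identifier-handling failures."""


class MintingError(IdentifierError):
    """A URI could not be minted (empty key, empty path segment, ...)."""


class ExpansionError(IdentifierError):
    """A shorthand could not be expanded (unknown prefix, bare token)."""


def percent_encode(text: str) -> str:
    """Percent-encode ``text`` for use as a URI path segment or fragment.

    Characters outside the RFC 3986 unreserved set are encoded as
    uppercase ``%XX`` escapes of their UTF-8 bytes.  Sequences that
    already look like an escape (``%`` followed by two hex digits) are
    passed through verbatim so that pre-encoded keys are not
    double-encoded.
    """
    out: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "%" and i + 3 <= n and all(c in _HEX for c in text[i + 1 : i + 3]):
            out.append(text[i : i + 3])
            i += 3
            continue
        if ch in _UNRESERVED:
            out.append(ch)
        else:
            out.extend(f"%{b:02X}" for b in ch.encode("utf-8"))
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class NamespaceMap:
    """Prefix-to-namespace bindings plus an optional document base IRI.

    ``prefixes`` maps shorthand prefixes (``tma``, ``dc``) to namespace
    IRIs *including* any trailing ``#`` or ``/``; expansion is plain
    concatenation.  ``base`` anchors ``#fragment`` shorthands.
    """

    prefixes: Mapping[str, str] = field(default_factory=dict)
    base: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefixes", dict(self.prefixes))

    def with_base(self, base: str) -> "NamespaceMap":
        return NamespaceMap(prefixes=self.prefixes, base=base)

    def with_prefix(self, prefix: str, namespace: str) -> "NamespaceMap":
        merged = dict(self.prefixes)
        merged[prefix] = namespace
        return NamespaceMap(prefixes=merged, base=self.base)


@dataclass(frozen=True)
class UriPolicy:
    """How this publisher mints identifiers.

    ``authority`` is the HTTP host the publisher controls; identifiers
    must never be minted into someone else's namespace.
    ``path_templates`` maps a schema class to the collection path under
    which its members live (e.g. ``{"tma": ["tma"], "block": ["block"]}``),
    and ``key_rule`` is a human-readable note on what the key is
    (accession number, bank identifier, ...).
    """

    authority: str
    scheme: str = "http"
    path_templates: Mapping[str, Sequence[str]] = field(default_factory=dict)
    key_rule: str = "domain-meaningful identifier"

    def __post_init__(self) -> None:
        if not self.authority:
            raise MintingError("URI policy requires a non-empty authority")
        object.__setattr__(
            self,
            "path_templates",
            {k: tuple(v) for k, v in dict(self.path_templates).items()},
        )

    def path_for(self, schema_class: str) -> Sequence[str]:
        return self.path_templates.get(schema_class, (schema_class,))

    def mint(self, schema_class: str, key: str) -> Iri:
        """Mint the identifier for an entity of ``schema_class``."""
        return mint_uri(self, self.path_for(schema_class), key)


def mint_uri(policy: UriPolicy, collection_path: Sequence[str], key: str) -> Iri:
    """Mint ``scheme://authority/<collection_path>/<encoded key>``.

    Deterministic: the same policy, path, and key always yield the same
    IRI, which is what keeps published identifiers stable.
    """
    if not key:
        raise MintingError("cannot mint a URI from an empty key")
    for seg in collection_path:
        if not seg:
            raise MintingError("collection path contains an empty segment")
    encoded = percent_encode(key)
    if not encoded:
        raise MintingError(f"key {key!r} percent-encodes to the empty string")
    segments = [percent_encode(s) for s in collection_path] + [encoded]
    return Iri(f"{policy.scheme}://{policy.authority}/" + "/".join(segments))


def _looks_absolute(value: str) -> bool:
    scheme, sep, rest = value.partition(":")
    return bool(sep) and scheme.isalpha() and rest.startswith("//")


def expand(shorthand: str, nsmap: NamespaceMap) -> Iri:
    """Expand a ``#fragment`` or ``prefix:local`` shorthand to an IRI.

    ``#f`` becomes ``base + "#f"`` (the fragment is assumed to belong to
    the document base); ``p:l`` becomes the bound namespace concatenated
    with ``l``; absolute IRIs pass through unchanged.
    """
    if shorthand.startswith("#"):
        if nsmap.base is None:
            raise ExpansionError(
                f"cannot expand {shorthand!r}: namespace map has no base IRI"
            )
        return Iri(nsmap.base + shorthand)
    if _looks_absolute(shorthand):
        return Iri(shorthand)
    prefix, sep, local = shorthand.partition(":")
    if sep:
        try:
            return Iri(nsmap.prefixes[prefix] + local)
        except KeyError:
            raise ExpansionError(f"unknown namespace prefix {prefix!r}") from None
    raise ExpansionError(
        f"{shorthand!r} is neither '#fragment', 'prefix:local', nor an absolute IRI"
    )


def compact(iri: str, nsmap: NamespaceMap) -> str:
    """Inverse of :func:`expand`: longest matching namespace wins.

    The document base compacts to a bare ``#fragment``.  An IRI matching
    no binding is returned unchanged, so ``expand(compact(x)) == x``
    always holds.
    """
    best: tuple[int, str] | None = None
    if nsmap.base is not None and iri.startswith(nsmap.base + "#"):
        best = (len(nsmap.base) + 1, "")
    for prefix, ns in nsmap.prefixes.items():
        if iri.startswith(ns) and len(iri) > len(ns):
            if best is None or len(ns) > best[0]:
                best = (len(ns), prefix)
    if best is None:
        return iri
    length, prefix = best
    if prefix == "":
        return "#" + iri[length:]
    return f"{prefix}:{iri[length:]}"


def is_internal(iri: str, base: str) -> bool:
    """True iff ``iri`` is the document itself or a fragment of it."""
    return iri == base or iri.startswith(base + "#")
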