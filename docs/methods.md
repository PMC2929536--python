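# Methods

## The data model

The library represents a tissue microarray as a five-level provenance
hierarchy: an array (`tma`) contains recipient blocks; a block is
sectioned into slides and holds cores drilled from donor blocks; each
slide carries sections of those cores at grid locations. Two abstract
classes partition the five concrete ones: `tma`, `block`, and `slide`
are `repository_product`s (dispensable physical artifacts a repository
hands out), while `core_in_block` and `core_on_slide` are
`experimental_component`s (the units measurements attach to). The
published listing of the vocabulary does not print which concrete
class sits under which parent; this assignment is the library's own,
is carried as data rather than code, and can be overridden
(`SchemaVocabulary.with_parent_override`).

Hierarchy edges come in four inverse pairs plus two unpaired
properties (`derived_from_core`, `donor_block`). The top-down member
of each pair is intended for whole-hierarchy documents; the bottom-up
member for documents that reference a parent living elsewhere. The
fifteen descriptive properties are deliberately modeled as
annotation-style properties whose values may be literals *or*
resources, because published usage employs both shapes for the same
property (a diagnosis as free text versus a pointer to an NCI
Thesaurus term); rejecting either shape would reject real documents.
Their value spaces (status, level, size, thickness, core spacing,
control) are undefined in the source material and are carried as
opaque strings.

## Identifiers

Identifiers follow the Linked Data conventions: mint HTTP URIs under
an authority you control, keep them stable, and key them with the
identifier that is meaningful in your domain (a bank accession such as
`RP2008-325`, not a database row id). `mint_uri` is a pure function of
(policy, collection path, key); keys are percent-encoded over the
RFC 3986 unreserved set, with already-encoded `%XX` sequences passed
through so pre-encoded keys are not double-encoded. Fragments are
encoded the same way as path keys — the convention for fragments is
unspecified in the source material, and symmetry keeps
`expand`/`compact` exact inverses.

One deliberate quirk: the Dublin Core namespace is configured as
`http://purl.org/dc/elements/1.1#` (hash form) rather than the slash
form DCMI itself uses, because that is how the vocabulary's published
shorthand table expands `dc:title`. The namespace map is configuration,
so deployments that prefer the canonical form can rebind it.

## Instance documents

RDF parsing and serialization are delegated to `rdflib` behind the
`TmaGraph` surface (a triple set plus namespace map). Serialization is
made deterministic by relabeling blank nodes canonically (fingerprint =
hash of a node's incident triples with blank identities masked, ties
broken by first occurrence in sorted order), sorting triples
lexicographically by subject, predicate, object over absolute IRIs,
and inserting them into the serializer in that order; the declared
base (`xml:base` / `@base`) makes documents self-contained. Literals
are never coerced or reformatted — a drill site `"78,90"` round-trips
byte-exact. Graph comparison is isomorphism up to a blank-node
bijection, checked exhaustively over the (few) blank nodes these
kilobyte-scale documents carry; the canonical-label fast path answers
almost every real case and the brute-force fallback guards the
symmetric corner cases.

Legacy documents that state typing with an `owl:Class` predicate are
accepted and normalized to `rdf:type` with a warning; `rdf:type` is
the only well-formed reading and is what the library always emits.

## Validation and inference

`validate` reports findings rather than raising. Structural rules are
errors: E1 untyped subject of a vocabulary object property, E2 domain
violation, E3 range violation, E4 a document fragment that is
referenced but described by no statement, E5 instantiation of an
abstract class. Stylistic rules are warnings: W1 legacy typing
predicate, W2/W3 location or drill-site values departing from the
conventional `D4` / `78,90` shapes, W4 unconventional annotation
usage (including multiple typing, where the first concrete type wins),
W5 an external reference (informational only). Range checks apply only
when the object is internal to the document and typed; external
references — donor blocks, diagnosis terms, experiment files — are by
design unresolved and are never errors.

The only inference implemented is inverse materialization: for each
statement over a paired property, add its mirror. This is idempotent
and information-preserving; `strip_inverses` removes one direction
again (refusing graphs that are not inverse-consistent, where
stripping would lose information). No other OWL reasoning is
performed, deliberately: the vocabulary's value is its shared names,
not deductive closure, and domain/range checking plus inverse closure
covers what exchange-document tooling needs.

## XML conversion

The three-step extraction pattern (query the source, store a
well-defined XML structure, convert to OWL) is implemented as a
programmatic transform over a pinned XML dialect (XSD in
`src/tmaowl/data/tma.xsd`): `tma > block > {slide, core}`, with cores
under a slide denoting sections and cores under a block denoting
embedded cores. A section names the block core it derives from; its
own minted identity is the slide-derived fragment `#<slide>-<location>`,
so the same core identifier may legitimately recur across slides (its
uniqueness scope is the slide). `donor_block`/`diagnosis_term` set on
a block act as defaults inherited by its cores, since the
corresponding vocabulary properties attach to cores, not blocks. The
converter emits hierarchy edges top-down by default (the convention
for whole-hierarchy documents), bottom-up or both on request. An XSLT
stylesheet is not the engine; the transform is plain code, which keeps
error reporting (dialect violations, identifier collisions) precise.

## Synthetic fixtures

The generator emulates the structural features of real TMA documents:
one array, multiple blocks with accession-style keys, spreadsheet-style
grid locations (row letter + column number, matching the `D4`
convention) on an 8×12 default grid, integer drill sites drawn
uniformly from [0, 500] (matching the `78,90` shape; no coordinate
system is defined in the source material, so these are declared
conventions), repository names, per-core donor-block references into
simulated external documents, and diagnosis links into an
NCI-Thesaurus-style term pool. Defaults (2 blocks, 8×12 at 90% fill,
2 slides per block, ≈170 cores) sit at the small end of the
100–1000-core range typical of real arrays, keeping every generated
document under ~10 000 triples so full round-trip suites run in
seconds. Everything derives from a single integer seed; equal seeds
give byte-identical documents.

What the generator does **not** emulate: staining or scoring results
(results are opaque tokens), clinical data models, image data, and
skewed real-world identifier schemes. Passing tests therefore
demonstrate structural and serialization correctness on well-formed
hierarchies, not robustness to arbitrarily messy institutional
exports.

`mutate` injects exactly one seeded corruption per named validation
rule (drop a typing statement, rewire a domain, retarget a range onto
a wrongly-typed internal node, dangle a fragment reference, retype a
node abstract), giving the validator a labeled detection suite with
ground truth by construction.

## Numerical and procedural choices

- Canonical triple order is plain lexicographic (subject, predicate,
  object) over absolute IRIs, blank nodes first; no hierarchy-aware
  ordering.
- Auto-minted term-link nodes use the smallest free `#<property><n>`
  counter, matching the `#diagnosis1` naming of the worked example.
- The property connecting a core-on-slide to an externally described
  experiment is not named in the source material; `assay` is used (the
  only assay-flavored property in the vocabulary) and is configurable
  per call.
- The acceptance script sizes its synthetic runs at 20 documents of up
  to 5 blocks on 8×12 grids with fill spanning 0–1 for round-trip
  checks, 50 mutated plus 20 clean documents for detection, and 8
  documents for dual-construction equivalence — small enough to run in
  seconds while exercising every code path, including empty and full
  grids.

## Known limitations

- No HTTP dereferencing: resolvability of minted URIs is the
  publisher's duty; the library never fetches anything.
- No OWL-DL reasoning, cardinality axioms, or imports closure.
- Blank-node canonicalization is fingerprint-based, not a full graph
  canonicalization; it is deterministic and adequate for documents
  with a handful of blank nodes, which is the regime these documents
  occupy.
- The subclass placement under the two abstract parents is an informed
  choice, not a reproduction of the hosted schema file, and may differ
  from other deployments; it is configurable for that reason.
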