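# tmaowl

Tooling for sharing tissue-microarray (TMA) data as Linked Data, built
around a minimal OWL vocabulary for TMA provenance.

A TMA is a paraffin block carrying hundreds of tissue cores arrayed in
a grid; it is sectioned into near-identical slides that are dispensed
across laboratories and reused for years. Sharing the resulting
experimental data runs into a naming problem: local XML tags and local
database keys mean nothing outside the institution that coined them.
`tmaowl` addresses this for pathology-informatics and biobank
developers by pairing globally scoped HTTP identifiers with a small
shared RDF/OWL vocabulary, so that a statement like *"the core at D4 on
slide 058 was drilled from donor block RP2007-228"* means the same
thing in every system that reads it.

## The vocabulary

Seven classes describe the physical hierarchy — two abstract parents
(`repository_product`, `experimental_component`) and five concrete
classes (`tma`, `block`, `slide`, `core_in_block`, `core_on_slide`) —
in the namespace `http://bioontology.org/ontologies/tma-minimal#`.
Ten object properties wire the hierarchy together, four of them as
OWL inverse pairs:

| top-down (container → part) | bottom-up (part → parent) |
|---|---|
| `includes_block` | `included_in_tma` |
| `includes_slide` | `cut_from_block` |
| `block_includes_core` | `included_in_block` |
| `slide_includes_core` | `affixed_to_slide` |

`derived_from_core` ties a section on a slide to the block core it was
cut from, and `donor_block` points (externally, never resolved) at the
patient block a core was drilled from. Fifteen annotation properties
(`location`, `drill_site`, `repository`, `diagnosis`, `result`, ...)
carry descriptive values, each accepting either a literal or a
resource — a diagnosis may be a string or a pointer to an external
ontology term such as an NCI Thesaurus class.

The library provides the vocabulary as data and as an emitted OWL
schema document; a typed in-memory hierarchy model with lossless
triple projection; Linked-Data identifier minting and CURIE/fragment
expansion; RDF/XML and Turtle instance-document I/O with canonical
ordering and graph isomorphism; a validator with inverse-property
materialization; an XML→OWL converter for well-structured hierarchy
exports; external-ontology term linking; and a seeded synthetic-TMA
generator for testing.

## Worked example

The canonical example describes a one-core TMA: array `tma/000001`
holds block `RP2008-325`; slide 058 was cut from the block; the core
drilled at site (78,90) appears at grid location D4 on the slide and
carries an NCI Thesaurus diagnosis.

```python
from tmaowl import UriPolicy, TmaModel, to_graph, validate
from tmaowl.examples import example_nsmap
from tmaowl.external_links import link_term

policy = UriPolicy(authority="www.institutionXYZ.org",
                   path_templates={"tma": ["tma"], "block": ["block"]})
base = "http://www.the_url_here.org/tma_example1.rdf"

m = TmaModel()
m.add_node("tma", policy.mint("tma", "000001"),
           {"http://purl.org/dc/elements/1.1#title": "All-Purpose Tissue Array"})
m.add_node("block", policy.mint("block", "RP2008-325"))
m.add_node("slide", base + "#slide058")
m.add_node("core_in_block", base + "#coreD4",
           {"repository": "Generic Tissue Bank", "drill_site": "78,90"})
m.add_node("core_on_slide", base + "#slide058-D4", {"location": "D4"})
m.add_edge(policy.mint("tma", "000001"), "includes_block",
           policy.mint("block", "RP2008-325"))
m.add_edge(policy.mint("block", "RP2008-325"), "includes_slide", base + "#slide058")
m.add_edge(policy.mint("block", "RP2008-325"), "block_includes_core", base + "#coreD4")
m.add_edge(base + "#slide058", "slide_includes_core", base + "#slide058-D4")
m.add_edge(base + "#coreD4", "donor_block", policy.mint("block", "RP2007-228"))
m.add_edge(base + "#slide058-D4", "derived_from_core", base + "#coreD4")

g = link_term(to_graph(m, example_nsmap()), base + "#coreD4", "diagnosis",
              "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma",
              "#diagnosis1")
print(len(g), validate(g).valid)
```

prints

```
18 True
```

18 is the number of statements in the instance document (one typing
triple per resource, one per annotation value, one per hierarchy edge,
plus the two-triple diagnosis link), and `True` says the document uses
every class and property within its declared domain and range. The
same document ships pre-serialized as `examples/tma_example1.rdf`
(and `.ttl`), and the identifier rules are available on the command
line:

```sh
$ tmaowl mint --authority www.institutionXYZ.org --path tma/rdf --key 123456
http://www.institutionXYZ.org/tma/rdf/123456
$ tmaowl validate examples/tma_example1.rdf
valid: true
...
$ tmaowl triples examples/tma_example1.rdf | wc -l
18
```

Other commands: `tmaowl schema --emit tma_minimal.owl` regenerates the
OWL schema document, `tmaowl convert array.xml --out array.owl` runs
the XML→OWL pipeline, and `tmaowl synth --seed 42 ...` generates
synthetic documents (optionally with one seeded corruption via
`--mutate E1..E5` for validator testing).

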