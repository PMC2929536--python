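"""Deterministic synthetic TMA fixtures.

Real TMA instance documents are institution data; tests and examples
instead run on generated hierarchies that emulate their structure:
multi-block arrays, grid-addressed cores ("D4" style locations on an
8x12 default grid, matching typical recipient-block layouts of a few
hundred cores), integer drill-site coordinates ("78,90" style),
repository names, donor-block references into other (simulated, never
fetched) documents, and diagnosis links to external-ontology terms.

Everything is a pure function of the generation spec and its seed, so
any document can be regenerated from two integers.  :func:`mutate`
injects exactly one seeded structural corruption of a named kind,
giving the validator a ground-truth detection suite.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from urllib.parse import unquote

from .identifiers import Iri, NamespaceMap, UriPolicy
from .model import TmaModel, to_graph
from .rdf_io import RDF_TYPE, Literal, TmaGraph, Triple, triple_key
from .schema import DC_NS, build_schema

__all__ = [
    "SynthSpec",
    "SynthError",
    "MutationError",
    "default_policy",
    "generate_model",
    "generate_graph",
    "render_xml",
    "mutate",
]

#: Simulated external diagnosis terms (NCI-Thesaurus-style IRIs; the
#: ontology itself is never fetched).
DEFAULT_DIAGNOSIS_POOL = (
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Breast_Carcinoma",
    "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Colon_Carcinoma",
)

_REPOSITORIES = (
    "Generic Tissue Bank",
    "Synthetic Mesothelioma Bank",
    "Example University Tissue Repository",
)


class SynthError(ValueError):
    pass


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    """Shape of a generated TMA.

    Defaults give two 8x12 blocks at 90% fill — a small but realistic
    array of ~170 cores, within the few-hundred-core range typical of
    recipient blocks — with two slides cut per block.
    """

    seed: int = 0
    n_blocks: int = 2
    grid_rows: int = 8
    grid_cols: int = 12
    slides_per_block: int = 2
    fill_rate: float = 0.9
    diagnosis_pool: tuple[str, ...] = DEFAULT_DIAGNOSIS_POOL
    annotation_noise: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.grid_rows <= 26:
            raise SynthError("grid_rows must be between 0 and 26 (row letters)")
        if not 0.0 <= self.fill_rate <= 1.0:
            raise SynthError("fill_rate must lie in [0, 1]")
        if min(self.n_blocks, self.grid_cols, self.slides_per_block) < 0:
            raise SynthError("counts must be non-negative")


def default_policy(authority: str = "www.example-tma.org") -> UriPolicy:
    return UriPolicy(
        authority=authority,
        path_templates={"tma": ["tma"], "block": ["block"]},
    )


def _base_for(policy: UriPolicy, tma_id: str) -> str:
    return f"{policy.scheme}://{policy.authority}/docs/tma{tma_id}.rdf"


def generate_model(spec: SynthSpec, policy: UriPolicy | None = None,
                   base: str | None = None) -> TmaModel:
    """Generate a typed TMA hierarchy from a spec (seeded, reproducible).

    One array; ``n_blocks`` blocks, each with ``slides_per_block``
    slides and ``round(fill_rate * rows * cols)`` cores at distinct grid
    locations; every slide carries one section per block core, linked
    ``derived_from_core``.  The TMA and its blocks get policy-minted
    absolute identifiers; slides and cores are fragments of the
    document base.
    """
    policy = policy if policy is not None else default_policy()
    rng = random.Random(spec.seed)
    n_cells = spec.grid_rows * spec.grid_cols
    n_cores = round(spec.fill_rate * n_cells)
    if n_cores > n_cells:
        raise SynthError(
            f"cannot place {n_cores} cores on a {spec.grid_rows}x"
            f"{spec.grid_cols} grid"
        )

    model = TmaModel()
    tma_id = f"{spec.seed:06d}"
    if base is None:
        base = _base_for(policy, tma_id)
    tma_iri = policy.mint("tma", tma_id)
    model.add_node("tma", tma_iri, {
        DC_NS + "title": f"Synthetic Tissue Array {tma_id}",
        "repository": rng.choice(_REPOSITORIES),
    })

    cells = [
        f"{string.ascii_uppercase[r]}{c + 1}"
        for r in range(spec.grid_rows)
        for c in range(spec.grid_cols)
    ]
    block_keys: list[str] = []
    while len(block_keys) < spec.n_blocks:
        key = f"RP{rng.randint(2000, 2010)}-{rng.randint(100, 999)}"
        if key not in block_keys:
            block_keys.append(key)

    slide_counter = 0
    for block_key in block_keys:
        block_iri = policy.mint("block", block_key)
        model.add_node("block", block_iri)
        model.add_edge(tma_iri, "includes_block", block_iri)
        locations = sorted(rng.sample(cells, n_cores))
        core_iris: dict[str, Iri] = {}
        for loc in locations:
            core_key = f"{block_key}-core{loc}"
            core_iri = Iri(f"{base}#{core_key}")
            annotations = {
                "drill_site": f"{rng.randint(0, 500)},{rng.randint(0, 500)}",
                "repository": rng.choice(_REPOSITORIES),
            }
            if spec.diagnosis_pool and rng.random() < 0.5:
                annotations["diagnosis"] = Iri(rng.choice(spec.diagnosis_pool))
            if spec.annotation_noise:
                annotations["status"] = f"status-{rng.randint(0, 9)}"
            model.add_node("core_in_block", core_iri, annotations)
            core_iris[loc] = core_iri
            model.add_edge(block_iri, "block_includes_core", core_iri)
            donor = policy.mint("block", f"DN{rng.randint(10000, 99999)}")
            model.add_edge(core_iri, "donor_block", donor)
        for _ in range(spec.slides_per_block):
            slide_counter += 1
            slide_key = f"slide{slide_counter:03d}"
            slide_iri = Iri(f"{base}#{slide_key}")
            model.add_node("slide", slide_iri)
            model.add_edge(block_iri, "includes_slide", slide_iri)
            for loc in locations:
                section_iri = Iri(f"{base}#{slide_key}-{loc}")
                model.add_node("core_on_slide", section_iri,
                               {"location": loc})
                model.add_edge(slide_iri, "slide_includes_core", section_iri)
                model.add_edge(section_iri, "derived_from_core",
                               core_iris[loc])
    return model


def generate_graph(spec: SynthSpec, policy: UriPolicy | None = None,
                   ) -> TmaGraph:
    """Convenience: generate a model and project it to triples."""
    policy = policy if policy is not None else default_policy()
    base = _base_for(policy, f"{spec.seed:06d}")
    model = generate_model(spec, policy, base=base)
    graph = to_graph(model)
    graph.nsmap = graph.nsmap.with_base(base)
    return graph


# -- XML rendering (feeds the XML->OWL converter) ----------------------


def _key_of(iri: str) -> str:
    """Recover the minting key: last path segment or fragment."""
    if "#" in iri:
        return unquote(iri.rsplit("#", 1)[1])
    return unquote(iri.rstrip("/").rsplit("/", 1)[1])


def render_xml(model: TmaModel) -> bytes:
    """Render a generated model in the converter's XML dialect.

    Inverse of the XML->OWL conversion under the same URI policy:
    ``convert(parse_tma_xml(render_xml(m)), config)`` is isomorphic to
    ``to_graph(m)``.
    """
    from lxml import etree

    def literal_of(node, prop):
        values = node.annotations.get(prop, [])
        return str(values[0]) if values else None

    vocab = model.vocab
    arrays = model.arrays
    if len(arrays) != 1:
        raise SynthError("XML rendering expects exactly one tma node")
    tma = arrays[0]
    root = etree.Element("tma", identifier=_key_of(tma.iri))
    title = literal_of(tma, DC_NS + "title")
    if title:
        root.set("title", title)
    creator = literal_of(tma, DC_NS + "creator")
    if creator:
        root.set("creator", creator)
    repository = literal_of(tma, "repository")
    if repository:
        root.set("repository", repository)

    edges = sorted(model.edges, key=lambda e: (e[1], str(e[0]), str(e[2])))

    def objects_of(subject, prop):
        return [o for s, p, o in edges if s == subject and p == prop]

    derived_from = {
        s: o for s, p, o in model.edges if p == "derived_from_core"
    }

    for block in [model.nodes[o] for o in objects_of(tma.iri, "includes_block")]:
        block_el = etree.SubElement(root, "block",
                                    identifier=_key_of(block.iri))
        for core_iri in objects_of(block.iri, "block_includes_core"):
            core = model.nodes[core_iri]
            core_el = etree.SubElement(block_el, "core",
                                       identifier=_key_of(core.iri))
            for attr in ("location", "drill_site"):
                v = literal_of(core, attr)
                if v:
                    core_el.set(attr, v)
            donors = objects_of(core.iri, "donor_block")
            if donors:
                core_el.set("donor_block", str(donors[0]))
            terms = [v for v in core.annotations.get("diagnosis", [])
                     if isinstance(v, Iri)]
            if terms:
                core_el.set("diagnosis_term", str(terms[0]))
            for prop, values in sorted(core.annotations.items()):
                if prop in ("location", "drill_site", "diagnosis"):
                    continue
                if prop.startswith("http"):
                    continue
                for v in values:
                    child = etree.SubElement(core_el, prop)
                    child.text = str(v)
        for slide_iri in objects_of(block.iri, "includes_slide"):
            slide = model.nodes[slide_iri]
            slide_el = etree.SubElement(block_el, "slide",
                                        identifier=_key_of(slide.iri))
            for section_iri in objects_of(slide.iri, "slide_includes_core"):
                section = model.nodes[section_iri]
                attrs = {"identifier": _key_of(derived_from[section.iri])
                         if section.iri in derived_from
                         else _key_of(section.iri)}
                loc = literal_of(section, "location")
                if loc:
                    attrs["location"] = loc
                etree.SubElement(slide_el, "core", **attrs)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# -- seeded structural corruptions -------------------------------------


def mutate(graph: TmaGraph, rule_id: str, seed: int = 0) -> TmaGraph:
    """Inject exactly one corruption of the named validation-rule kind.

    E1 drops a typing statement; E2 rewires an edge onto a
    wrongly-typed subject; E3 retargets an edge onto a wrongly-typed
    internal object; E4 adds a reference to a fragment nobody
    describes; E5 retypes a node with an abstract class.
    """
    vocab = build_schema()
    ns = vocab.namespace
    rng = random.Random(seed)
    base = graph.nsmap.base

    def local(p) -> str | None:
        return str(p)[len(ns):] if str(p).startswith(ns) else None

    types: dict = {}
    for t in graph.triples:
        if t.predicate == RDF_TYPE:
            l = local(str(t.object))
            if l in vocab.concrete_class_names:
                types[t.subject] = l

    object_prop_triples = sorted(
        (
            t
            for t in graph.triples
            if (l := local(t.predicate)) is not None
            and vocab.has_property(l)
            and vocab.property(l).kind == "object"
        ),
        key=triple_key,
    )
    out = graph.copy()

    if rule_id == "E1":
        candidates = [t for t in object_prop_triples if t.subject in types]
        if not candidates:
            raise MutationError("no typed edge subject to untype")
        victim = rng.choice(candidates).subject
        out.triples = {
            t for t in out.triples
            if not (t.subject == victim and t.predicate == RDF_TYPE)
        }
        return out

    if rule_id == "E2":
        candidates = []
        for t in object_prop_triples:
            prop = vocab.property(local(t.predicate))
            if prop.domain == "any":
                continue
            wrong = sorted(
                s for s, cls in types.items() if cls != prop.domain
            )
            if wrong:
                candidates.append((t, wrong))
        if not candidates:
            raise MutationError("no edge can be rewired to a wrong subject")
        t, wrong = rng.choice(candidates)
        out.triples.discard(t)
        out.add(t.with_subject(rng.choice(wrong)))
        return out

    if rule_id == "E3":
        candidates = []
        for t in object_prop_triples:
            prop = vocab.property(local(t.predicate))
            if prop.range in ("external", "literal-or-resource"):
                continue
            wrong = sorted(
                s for s, cls in types.items()
                if cls != prop.range
                and base is not None
                and str(s).startswith(base + "#")
            )
            if wrong:
                candidates.append((t, wrong))
        if not candidates:
            raise MutationError("no edge can be retargeted internally")
        t, wrong = rng.choice(candidates)
        out.triples.discard(t)
        out.add(t.with_object(rng.choice(wrong)))
        return out

    if rule_id == "E4":
        if base is None:
            raise MutationError("graph has no base IRI for a dangling fragment")
        blocks = sorted(s for s, cls in types.items() if cls == "block")
        if not blocks:
            raise MutationError("no block node to hang a dangling core on")
        dangling = Iri(f"{base}#core-missing-{seed}")
        out.add(Triple(rng.choice(blocks), Iri(ns + "block_includes_core"),
                       dangling))
        return out

    if rule_id == "E5":
        typed = sorted(types, key=str)
        if not typed:
            raise MutationError("no typed node to retype")
        victim = rng.choice(typed)
        abstract = rng.choice(sorted(vocab.abstract_class_names))
        out.triples = {
            t for t in out.triples
            if not (t.subject == victim and t.predicate == RDF_TYPE)
        }
        out.add(Triple(victim, RDF_TYPE, Iri(ns + abstract)))
        return out

    raise MutationError(f"unknown mutation rule {rule_id!r}")
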