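import pytest

from tmaowl.examples import (
    EXAMPLE_BASE,
    example_graph,
    example_model,
    example_nsmap,
    example_policy,
)
from tmaowl.identifiers import NamespaceMap
from tmaowl.model import to_graph
from tmaowl.schema import DC_NS, TMA_NS, build_schema
from tmaowl.synth import SynthSpec, default_policy, generate_graph, generate_model


@pytest.fixture(scope="session")
def vocab():
    return build_schema()


@pytest.fixture()
def nsmap():
    return NamespaceMap(prefixes={"tma": TMA_NS, "dc": DC_NS},
                        base=EXAMPLE_BASE)


@pytest.fixture()
def policy():
    return example_policy()


@pytest.fixture()
def worked_model():
    return example_model()


@pytest.fixture()
def worked_graph():
    return example_graph()


def synth_graph(seed: int, **overrides):
    """A small seeded synthetic document graph (helper, not a fixture)."""
    spec = SynthSpec(seed=seed, n_blocks=1 + seed % 3, grid_rows=4,
                     grid_cols=6, slides_per_block=1,
                     fill_rate=(seed % 5) / 4 or 0.5, **overrides)
    return generate_graph(spec)


def synth_model(seed: int, **overrides):
    spec = SynthSpec(seed=seed, n_blocks=1 + seed % 3, grid_rows=4,
                     grid_cols=6, slides_per_block=1,
                     fill_rate=(seed % 5) / 4 or 0.5, **overrides)
    policy = default_policy()
    base = f"http://{policy.authority}/docs/tma{seed:06d}.rdf"
    model = generate_model(spec, policy, base=base)
    graph = to_graph(model)
    graph.nsmap = graph.nsmap.with_base(base)
    return model, graph
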