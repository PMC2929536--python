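"""Configuration: namespace map, URI policy, and generator settings.

A single YAML or JSON file configures everything identity-related —
which prefixes documents abbreviate with, the document base IRI, and
the authority/path templates under which this publisher mints
identifiers — plus the synthetic-generator shape.  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .identifiers import NamespaceMap, UriPolicy
from .schema import DC_NS, TMA_NS
from .synth import SynthSpec

__all__ = ["SynthSection", "CliConfig", "load_config", "DEFAULT_PREFIXES"]

DEFAULT_PREFIXES = {"tma": TMA_NS, "dc": DC_NS}


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_blocks: int = 2
    grid_rows: int = 8
    grid_cols: int = 12
    slides_per_block: int = 2
    fill_rate: float = 0.9
    annotation_noise: bool = False

    def to_spec(self, seed: int | None = None) -> SynthSpec:
        return SynthSpec(
            seed=self.seed if seed is None else seed,
            n_blocks=self.n_blocks,
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            slides_per_block=self.slides_per_block,
            fill_rate=self.fill_rate,
            annotation_noise=self.annotation_noise,
        )


class CliConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prefixes: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_PREFIXES))
    base: str | None = None
    authority: str = "www.example-tma.org"
    scheme: str = "http"
    path_templates: dict[str, list[str]] = Field(
        default_factory=lambda: {"tma": ["tma"], "block": ["block"]}
    )
    direction: str = "top_down"
    synth: SynthSection = Field(default_factory=SynthSection)
    log_level: str = "INFO"

    def to_nsmap(self) -> NamespaceMap:
        return NamespaceMap(prefixes=self.prefixes, base=self.base)

    def to_policy(self) -> UriPolicy:
        return UriPolicy(
            authority=self.authority,
            scheme=self.scheme,
            path_templates=self.path_templates,
        )


def load_config(path: str | Path | None = None) -> CliConfig:
    """Load a YAML/JSON config file; with no path, return defaults."""
    if path is None:
        return CliConfig()
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return CliConfig.model_validate(data or {})
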