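"""Flat key/value run configuration.

The configuration file is a flat YAML mapping with the keys below (all
optional; defaults are the yeast genome-wide screen layout used throughout):

=================  =======================================  ========
key                meaning                                  default
=================  =======================================  ========
n_targets          LOF target loci                          4800
n_controls         control guides (pooled)                  800
guides_per_target  guides per locus                         8
depth              expected reads per guide                 100
generations        competition length (generations)         26
ploidy             1 (haploid) or 2 (diploid)               1
alpha              detection significance level             0.05
iterations         Monte-Carlo iterations per point         1000
seed               root random seed                         0
=================  =======================================  ========
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .screen_model import ScreenDesign

__all__ = ["RunConfig", "load_config"]

_KEYS = {
    "n_targets", "n_controls", "guides_per_target", "depth",
    "generations", "ploidy", "alpha", "iterations", "seed",
}


@dataclass(frozen=True)
class RunConfig:
    n_targets: int = 4800
    n_controls: int = 800
    guides_per_target: int = 8
    depth: int = 100
    generations: int = 26
    ploidy: int = 1
    alpha: float = 0.05
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.design()  # validates the layout fields

    def design(self) -> ScreenDesign:
        return ScreenDesign(
            n_targets=self.n_targets,
            n_controls=self.n_controls,
            guides_per_target=self.guides_per_target,
            depth=self.depth,
            generations=self.generations,
            ploidy=self.ploidy,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path, **overrides) -> RunConfig:
    """Load a flat YAML config, applying keyword overrides on top."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat key/value mapping")
    unknown = set(raw) - _KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)
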