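"""YAML run configuration.

A :class:`RunConfig` groups stage-specific parameter blocks (``cpm``,
``scan``, ``placement``, ``imaging``, ``postprocess``, ``eval``, ...)
plus one top-level ``seed`` from which every stochastic stage derives an
independent substream (see :mod:`spherogen.rng`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .rng import stage_rng, stage_seed

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger("spherogen")

_KNOWN_STAGES = (
    "phantom",
    "clean",
    "cpm",
    "scan",
    "placement",
    "imaging",
    "postprocess",
    "eval",
)


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def block(self, stage: str) -> dict[str, Any]:
        """Parameter block for *stage* (empty dict when absent)."""
        return dict(self.stages.get(stage, {}))

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def log_resolved(self) -> None:
        """Log the fully resolved parameter set and seed for reproducibility."""
        log.info("seed=%d", self.seed)
        for name in sorted(self.stages):
            log.info("stage %s: %s", name, self.stages[name])


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    seed = int(raw.pop("seed", 0))
    stages = {k: (v or {}) for k, v in raw.items() if isinstance(v, (dict, type(None)))}
    return RunConfig(seed=seed, stages=stages)
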