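"""Deterministic seed management.

One top-level seed; every stage derives an independent substream keyed by
its stage name, so adding or reordering stages never perturbs another
stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng", "derive_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """A stable 31-bit seed for *stage*, derived from the top-level seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), key])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_seed(seed: int, *keys: int) -> int:
    """A stable 31-bit seed derived from *seed* and integer subkeys."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """An independent :class:`numpy.random.Generator` for *stage*."""
    return np.random.default_rng(stage_seed(seed, stage))
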