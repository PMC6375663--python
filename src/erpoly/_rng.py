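"""Deterministic seed derivation.

A single master seed is fanned out into named child streams with
``numpy.random.SeedSequence``, so each stage of a pipeline (founder panel,
per-replicate drift, read sampling, null simulations, ...) is independently
reproducible: rerunning one stage with the same master seed and stage name
yields the same stream regardless of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed", "spawn_rngs"]


def _stage_key(name: str) -> int:
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(name.encode("utf8"))


def child_seed(master_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence for a named stage derived from the master seed."""
    return np.random.SeedSequence(entropy=int(master_seed) % (2**31),
                                  spawn_key=(_stage_key(stage), int(index)))


def child_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for a named stage derived from the master seed."""
    return np.random.default_rng(child_seed(master_seed, stage, index))


def spawn_rngs(master_seed: int, stage: str, n: int) -> list[np.random.Generator]:
    """n independent generators for replicated sub-stages (one per replicate)."""
    return [child_rng(master_seed, stage, i) for i in range(n)]
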