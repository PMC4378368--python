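"""Deterministic seed derivation.

A single master seed drives every stochastic stage of the pipeline.  Each
stage derives its own independent stream by hashing the stage name into a
:class:`numpy.random.SeedSequence`, so reordering or skipping stages never
perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed_sequence", "stage_rng", "splitmix64"]


def derive_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage, derived from the master seed."""
    tag = zlib.crc32(stage.encode("utf-8")) & 0xFFFFFFFF
    return np.random.SeedSequence(entropy=[int(master_seed) & 0x7FFFFFFF, tag])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage."""
    return np.random.default_rng(derive_seed_sequence(master_seed, stage))


_GAMMA = np.uint64(0x9E3779B97F4A7C15)


def splitmix64(x: np.ndarray | int) -> np.ndarray | np.uint64:
    """Vectorized splitmix64 finalizer; fast stateless integer hashing.

    Used to give every (tree, node, feature) triple a stable pseudo-random
    priority, independent of how many features exist.
    """
    with np.errstate(over="ignore"):
        z = (np.uint64(x) + _GAMMA) * np.uint64(1)
        z = np.asarray(z, dtype=np.uint64)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z
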