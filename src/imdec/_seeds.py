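"""Deterministic fan-out of one master seed into named substreams.

Every stochastic stage (event ordering, BOLD noise, label scrambling,
gaze simulation) draws from its own named substream so that changing one
stage's consumption pattern never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int | None, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``master_seed``.

    ``None`` yields a nondeterministic generator.  The substream key is a
    CRC32 of the name, so streams are stable across sessions and platforms.
    """
    if master_seed is None:
        return np.random.default_rng()
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    )
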