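"""Stable, label-keyed RNG streams.

Every stochastic step draws from its own stream derived from the master
seed plus string labels via SHA-256, so adding a tube or sample never
perturbs another's draws and results are reproducible across processes.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream_rng", "stream_seed"]


def stream_seed(seed: int, *labels: str) -> int:
    key = "|".join((str(int(seed)),) + tuple(labels)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little")


def stream_rng(seed: int, *labels: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(seed, *labels))
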