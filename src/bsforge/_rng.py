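"""Seed bookkeeping: one master seed expands to named, independent substreams.

Each pipeline stage (treatment, pcr, reads, analysis fixtures, ...) derives its
own 31-bit seed from ``(master_seed, name)`` via SHA-256, so changing the seed
of one stage never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "substream_rng"]


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit seed for the named substream."""
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    """A numpy Generator seeded from the named substream."""
    return np.random.default_rng(substream_seed(master_seed, name))
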