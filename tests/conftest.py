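"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from bsforge.analysis import ConvertedReference, Pileup, insilico_convert

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

MATCH, MISMATCH, GAP = 1, -2, -3


def make_pileup(ref_seq: str, obs: dict) -> Pileup:
    """Craft a pileup directly: ``obs`` maps position -> {base: count}."""
    ref = insilico_convert(ref_seq)
    counts = np.zeros((len(ref_seq), 4), dtype=np.int64)
    for pos, bases in obs.items():
        for base, n in bases.items():
            counts[pos, BASE_INDEX[base]] = n
    return Pileup(ref=ref, counts=counts)


def exhaustive_dp_score(read: str, ref: str) -> int:
    """Independent full-matrix semi-global DP oracle on collapsed strings:
    read global, reference local, match +1 / mismatch -2 / linear gap -3."""
    read = read.replace("C", "T")
    ref = ref.replace("C", "T")
    n, L = len(read), len(ref)
    prev = [0] * (L + 1)
    for i in range(1, n + 1):
        cur = [prev[0] + GAP]
        for j in range(1, L + 1):
            sub = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
            cur.append(max(prev[j - 1] + sub, prev[j] + GAP, cur[j - 1] + GAP))
        prev = cur
    return max(prev)


def mutate_read(rng: np.random.Generator, ref: str, read_len: int) -> str:
    """Sample a read from a reference with substitutions and a few indels
    (the instance generator for aligner-oracle checks)."""
    start = int(rng.integers(0, max(1, len(ref) - read_len)))
    read = list(ref[start : start + read_len])
    # substitutions
    for i in range(len(read)):
        if rng.random() < 0.08:
            read[i] = "ACGT"[rng.integers(4)]
    # up to two short indels
    for _ in range(int(rng.integers(0, 3))):
        if len(read) > 4 and rng.random() < 0.5:
            del read[int(rng.integers(len(read)))]
        else:
            read.insert(int(rng.integers(len(read) + 1)), "ACGT"[rng.integers(4)])
    return "".join(read) or "A"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
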