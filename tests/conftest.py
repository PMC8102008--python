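"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from icespread.synthetic_data import random_sequence

_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
]


def make_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A random intact ORF: ATG, sense codons, one terminal stop."""
    idx = rng.integers(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


def edit_distance_dp(a: str, b: str) -> int:
    """Independent quadratic-time unit-cost edit distance (row DP, numpy)."""
    bi = np.frombuffer(b.encode(), dtype="S1")
    prev = np.arange(len(b) + 1)
    for ca in a.encode():
        cur = np.empty_like(prev)
        cur[0] = prev[0] + 1
        sub = prev[:-1] + (bi != bytes([ca]).decode().encode())
        # cur[j] = min(prev[j] + 1, sub[j-1], cur[j-1] + 1); resolve the
        # left-to-right dependency with a running scan
        best = np.minimum(prev[1:] + 1, sub)
        run = cur[0]
        out = np.empty(len(b), dtype=prev.dtype)
        for j in range(len(b)):
            run = min(run + 1, best[j])
            out[j] = run
        cur[1:] = out
        prev = cur
    return int(prev[-1])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def background_100kb():
    return random_sequence(np.random.default_rng(77), 100_000)
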