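"""Shared helpers: alphabet, seeded RNG streams, random sequence generation."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_SEQUENCE_LENGTH = 40


def check_sequence(seq: str) -> str:
    """Validate that *seq* is a non-empty string over {A,C,G,T}."""
    if not seq or any(c not in BASE_INDEX for c in seq):
        raise ValueError(f"sequence must be non-empty over ACGT, got {seq!r}")
    return seq


def derive_rng(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic per-stage RNG stream.

    A single experiment-level seed fans out into independent streams keyed by
    string tags, so stages can be re-run in isolation yet reproducibly.
    Derived entropy words stay below 2**31.
    """
    words = [int(seed) % (2**31)]
    words += [zlib.crc32(t.encode()) % (2**31) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(words))


def random_sequences(
    n: int, length: int = DEFAULT_SEQUENCE_LENGTH, rng: np.random.Generator | None = None
) -> list[str]:
    """Generate *n* uniform random DNA sequences of the given length."""
    rng = rng if rng is not None else np.random.default_rng()
    idx = rng.integers(0, 4, size=(n, length))
    arr = np.frombuffer(BASES.encode(), dtype=np.uint8)[idx]
    return [row.tobytes().decode() for row in arr]
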