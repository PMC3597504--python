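"""Reproducible seed derivation.

Every stochastic operation in the package draws its randomness from a stream
derived from (global seed, operation name, replicate index).  Replicates are
therefore independently reproducible: re-running replicate 7 of an operation
does not require re-running replicates 0-6.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_int_seed"]


def _token_ints(tokens: tuple) -> list[int]:
    out = []
    for t in tokens:
        if isinstance(t, (int, np.integer)):
            out.append(int(t) & 0xFFFFFFFF)
        else:
            h = hashlib.blake2s(str(t).encode("utf-8"), digest_size=4).digest()
            out.append(int.from_bytes(h, "little"))
    return out


def derive_rng(seed: int, *tokens) -> np.random.Generator:
    """Generator for stream (seed, *tokens); stable across sessions."""
    ss = np.random.SeedSequence([int(seed)] + _token_ints(tokens))
    return np.random.default_rng(ss)


def derive_int_seed(seed: int, *tokens) -> int:
    """A positive 31-bit seed for libraries that want a scalar (e.g. msprime)."""
    rng = derive_rng(seed, *tokens)
    return int(rng.integers(1, 2**31 - 1))
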