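"""Low-level nucleotide sequence utilities.

Sequences are held as ``numpy.uint8`` arrays of base codes 0..3 (A, C, G, T).
Code 4 is reserved for N/unknown where it can occur (external FASTA input).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of codes 0..4 (A<->T, C<->G, N->N)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into base codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode base codes back into an uppercase nucleotide string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a coded sequence."""
    return _COMP[codes[::-1]]


def random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform-random coded genome of the given length."""
    return rng.integers(0, 4, size=length, dtype=np.uint8).copy()


def mutate_per_site(
    codes: np.ndarray, prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply independent per-site substitutions with probability ``prob``.

    Each selected site is replaced by one of the three other bases, chosen
    uniformly. Returns ``(mutated_copy, positions_changed)``.
    """
    out = codes.copy()
    if prob <= 0:
        return out, np.empty(0, dtype=np.int64)
    hits = np.flatnonzero(rng.random(codes.shape[0]) < prob)
    if hits.size:
        # shift by 1..3 (mod 4) guarantees a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out, hits


def mutate_at(
    codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute the given positions in place with a different base each."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size:
        codes[positions] = (
            codes[positions] + rng.integers(1, 4, size=positions.size)
        ) % 4
    return codes
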