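"""Deterministic pseudo-random reference genome.

A 200 Mb toy genome never needs to exist in memory: the base at any position
is a pure function of (chromosome, position, seed), computed with a
splitmix64-style integer hash.  This gives an O(1)-memory random-access
reference that is byte-stable across runs and platforms, which is all the
annotation and simulation layers require.
"""

from __future__ import annotations

import zlib

from autozyg.types import BASES

_MASK64 = 0xFFFFFFFFFFFFFFFF


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (x ^ (x >> 31)) & _MASK64


class ReferenceGenome:
    """Random-access synthetic reference with a fixed per-genome seed."""

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        chrom_key = zlib.crc32(chrom.encode())
        h = _splitmix64((chrom_key << 34) ^ (pos & _MASK64) ^ (self.seed << 1))
        return BASES[h & 3]

    def bases(self, chrom: str, positions) -> str:
        """Bases at an iterable of positions, concatenated in given order."""
        return "".join(self.base(chrom, p) for p in positions)

    def __call__(self, chrom: str, pos: int) -> str:
        return self.base(chrom, pos)
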