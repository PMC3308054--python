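"""Frequency-threshold genotype calling from read pileups.

The caller reproduces a simple but effective rule set for substitution
calling from per-position base counts:

* only bases at or above the quality cutoff ("high-quality" bases) are
  counted; a position needs at least ``min_depth`` (default 10) of them to be
  callable at all;
* with ``f`` the fraction of high-quality bases carrying the most frequent
  non-reference allele, ``f > hom_cut`` (default 0.75) is a homozygous
  variant, ``het_low <= f <= hom_cut`` (default 0.25..0.75, both ends
  inclusive) a heterozygous variant, and ``f < het_low`` no variant.

Ties between two equally frequent non-reference bases are broken
alphabetically so calls are deterministic.  Indels and secondary alternate
alleles are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from autozyg.types import BASES, PileupColumn, VariantCall


def high_quality_depth(column: PileupColumn) -> int:
    """Total high-quality bases at the position; low-quality bases never count."""
    return sum(column.counts_hi.values())


def allele_fraction_percent(alt_count: int, other_count: int) -> int:
    """Allele fraction as an integer percent, rounded half away from zero.

    This is the per-site "call rate" reported alongside each variant:
    89 alternate reads against 1 other read gives 99(%).
    """
    total = alt_count + other_count
    if total <= 0:
        raise ValueError("total read count must be positive")
    return math.floor(100 * alt_count / total + 0.5)


def call_genotype(
    column: PileupColumn,
    min_depth: int = 10,
    het_low: float = 0.25,
    hom_cut: float = 0.75,
) -> Optional[VariantCall]:
    """Call a genotype at one pileup column, or return ``None`` (no call).

    ``None`` covers both under-covered positions (high-quality depth below
    ``min_depth``) and positions whose top non-reference allele fraction is
    below ``het_low``; it is a value, not an error.
    """
    if not (0 < het_low < hom_cut < 1):
        raise ValueError("thresholds must satisfy 0 < het_low < hom_cut < 1")
    depth = high_quality_depth(column)
    if depth < min_depth:
        return None
    # Most frequent non-reference base; ties broken alphabetically.
    alt, alt_count = None, 0
    for base in BASES:
        if base == column.ref:
            continue
        n = column.counts_hi.get(base, 0)
        if n > alt_count:
            alt, alt_count = base, n
    if alt is None:
        return None
    f = alt_count / depth
    if f < het_low:
        return None
    zygosity = "hom" if f > hom_cut else "het"
    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        ref=column.ref,
        alt=alt,
        zygosity=zygosity,
        depth_hq=depth,
        alt_fraction=f,
        call_rate_percent=allele_fraction_percent(alt_count, depth - alt_count),
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Target-coverage statistics over the pileup stream (high-quality depth)."""

    n_positions: int
    mean_depth: float
    frac_ge_1x: float
    frac_ge_5x: float
    frac_ge_10x: float


def call_all(
    pileups: Iterable[PileupColumn],
    min_depth: int = 10,
    het_low: float = 0.25,
    hom_cut: float = 0.75,
) -> tuple[list[VariantCall], CoverageSummary]:
    """Call every column of a sorted pileup stream and summarize coverage.

    Raises ``ValueError`` if the stream is not sorted by (chrom, pos).
    Positions with no variant contribute to the coverage summary only.
    """
    calls: list[VariantCall] = []
    n = 0
    total_depth = 0
    ge1 = ge5 = ge10 = 0
    prev_key: Optional[tuple[str, int]] = None
    done_chroms: set[str] = set()
    for column in pileups:
        key = (column.chrom, column.pos)
        if prev_key is not None:
            if column.chrom == prev_key[0]:
                if column.pos <= prev_key[1]:
                    raise ValueError(
                        f"pileup stream not sorted: {prev_key} followed by {key}"
                    )
            else:
                done_chroms.add(prev_key[0])
                if column.chrom in done_chroms:
                    raise ValueError(
                        f"pileup stream interleaves chromosome {column.chrom}"
                    )
        prev_key = key
        depth = high_quality_depth(column)
        n += 1
        total_depth += depth
        ge1 += depth >= 1
        ge5 += depth >= 5
        ge10 += depth >= 10
        call = call_genotype(column, min_depth=min_depth, het_low=het_low, hom_cut=hom_cut)
        if call is not None:
            calls.append(call)
    if n == 0:
        summary = CoverageSummary(0, 0.0, 0.0, 0.0, 0.0)
    else:
        summary = CoverageSummary(
            n_positions=n,
            mean_depth=total_depth / n,
            frac_ge_1x=ge1 / n,
            frac_ge_5x=ge5 / n,
            frac_ge_10x=ge10 / n,
        )
    return calls, summary
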