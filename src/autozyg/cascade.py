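"""Recessive-candidate filtering cascade and AOH-region intersection.

The cascade shrinks an annotated exome call set to a handful of recessive
candidates by applying, in order: restrict to coding; drop known dbSNP
variants; drop known 1000 Genomes variants; keep homozygous calls; keep
missense changes (nonsense is a distinct class and is not kept by this
step); restrict to chromosomes that carry an AOH region; and finally keep
only variants lying inside an AOH interval.  Steps 2-5 are pure set filters,
so their order cannot change the final candidate list — only the
intermediate counts in the report.

Flanking-homozygosity support is the classic sanity check on a recessive
candidate in a consanguineous proband: an autozygous causal variant should
sit in an unbroken bed of homozygous array markers on both sides.
"""

from __future__ import annotations

import bisect
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from autozyg.types import (
    AnnotatedVariant,
    AOHRegion,
    CascadeReport,
    GenotypeRecord,
)

DEFAULT_STEPS = (
    "total",
    "coding",
    "not_in_dbsnp",
    "not_in_kg",
    "homozygous",
    "missense",
    "aoh_chromosomes",
    "within_aoh",
)


def intersect_aoh(
    variants: Sequence[AnnotatedVariant],
    regions: Iterable[AOHRegion],
) -> list[AnnotatedVariant]:
    """Keep variants inside an AOH interval (half-open: start <= pos < stop)."""
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        if region.stop > region.start:
            trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.stop
            )
    kept = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlaps_point(v.pos):
            kept.append(v)
    return kept


def _apply_step(
    name: str,
    variants: list[AnnotatedVariant],
    regions: list[AOHRegion],
) -> list[AnnotatedVariant]:
    if name == "total":
        return variants
    if name == "coding":
        return [v for v in variants if v.consequence != "noncoding"]
    if name == "not_in_dbsnp":
        return [v for v in variants if not v.in_dbsnp]
    if name == "not_in_kg":
        return [v for v in variants if not v.in_kg]
    if name == "homozygous":
        return [v for v in variants if v.zygosity == "hom"]
    if name == "missense":
        return [v for v in variants if v.consequence == "missense"]
    if name == "aoh_chromosomes":
        chroms = {r.chrom for r in regions}
        return [v for v in variants if v.chrom in chroms]
    if name == "within_aoh":
        return intersect_aoh(variants, regions)
    raise ValueError(f"unknown cascade step {name!r}")


def filter_cascade(
    variants: Sequence[AnnotatedVariant],
    aoh: Iterable[AOHRegion],
    steps: Sequence[str] = DEFAULT_STEPS,
) -> tuple[CascadeReport, list[AnnotatedVariant]]:
    """Run the filtering cascade; return the step report and the final list.

    ``steps`` must begin with ``"total"`` (the unfiltered input count);
    unknown step names raise ``ValueError``.
    """
    if not steps or steps[0] != "total":
        raise ValueError('cascade must start with the "total" step')
    regions = list(aoh)
    current = list(variants)
    rows: list[tuple[str, int]] = []
    for name in steps:
        current = _apply_step(name, current, regions)
        rows.append((name, len(current)))
    return CascadeReport(steps=tuple(rows)), current


def flanking_hom_support(
    variant,
    genotypes: Sequence[GenotypeRecord],
    required: int = 51,
    mode: str = "per_side",
) -> tuple[int, int, bool]:
    """Count consecutive homozygous markers flanking a variant position.

    Walks outward from the variant on its chromosome, left and right,
    counting homozygous markers until the first heterozygous one; missing
    genotypes are neutral (skipped without breaking the walk).  Under the
    default ``per_side`` reading the variant passes when each side reaches
    ``required`` homozygous markers; under ``total`` the two sides together
    must reach ``required``.

    ``variant`` may be anything with ``chrom`` and ``pos`` attributes.
    """
    if mode not in ("per_side", "total"):
        raise ValueError(f"unknown flanking mode {mode!r}")
    on_chrom = [g for g in genotypes if g.chrom == variant.chrom]
    positions = [g.pos for g in on_chrom]
    if positions != sorted(positions):
        raise ValueError("genotypes must be sorted by position")
    split = bisect.bisect_left(positions, variant.pos)

    def walk(indices) -> int:
        count = 0
        for i in indices:
            z = on_chrom[i].zygosity
            if z == "missing":
                continue
            if z == "het":
                break
            count += 1
        return count

    left = walk(range(split - 1, -1, -1))
    # A marker exactly at the variant position belongs to neither flank.
    start_right = split if split >= len(positions) or positions[split] != variant.pos else split + 1
    right = walk(range(start_right, len(on_chrom)))
    if mode == "per_side":
        ok = left >= required and right >= required
    else:
        ok = left + right >= required
    return left, right, ok
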