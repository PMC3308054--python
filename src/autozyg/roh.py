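"""Absence-of-heterozygosity (run-of-homozygosity) detection.

The scan is a deterministic greedy rule over sorted array markers, one
chromosome at a time: starting from the leftmost homozygous marker not yet
inside a reported run, the run is extended rightwards as far as it can go
while (a) the number of heterozygous markers inside stays at or below
``max_het_in_run`` and (b) no gap between consecutive informative markers
exceeds ``max_gap_bp``; trailing heterozygous markers are trimmed so every
run starts and ends on a homozygous marker.  A maximal extension is reported
iff it spans at least ``min_length_bp`` and contains at least ``min_markers``
informative markers; reported runs never overlap.  Missing genotypes (array
no-calls) are neutral throughout: they neither break a run, nor count toward
its marker total, nor enter the gap computation.

Run boundaries are the positions of the first and last marker, so a run's
reported length is ``stop - start``; interval logic downstream treats
``[start, stop)`` as half-open.
"""

from __future__ import annotations

from itertools import groupby
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from autozyg.types import AOHRegion, GeneModel, GenotypeRecord


def region_length(start: int, stop: int) -> int:
    """Length of a region in bp under the half-open convention: stop - start."""
    if stop < start:
        raise ValueError(f"stop {stop} precedes start {start}")
    return stop - start


def _check_sorted(genotypes: Sequence[GenotypeRecord]) -> None:
    for prev, cur in zip(genotypes, genotypes[1:]):
        if prev.chrom == cur.chrom:
            if cur.pos <= prev.pos:
                raise ValueError(
                    "genotypes must be sorted by (chrom, pos) with unique "
                    f"positions; saw {prev.chrom}:{prev.pos} then {cur.pos}"
                )


def scan_aoh(
    genotypes: Sequence[GenotypeRecord],
    min_markers: int = 50,
    min_length_bp: int = 3_000_000,
    max_het_in_run: int = 2,
    max_gap_bp: int = 1_000_000,
) -> list[AOHRegion]:
    """Detect homozygous runs in a sorted genotype table.

    Parameters default to values under which regions of the scale seen in
    consanguineous probands (several Mb, thousands of markers) pass
    comfortably while short chance runs of homozygosity do not.

    Raises ``ValueError`` on unsorted input; returns ``[]`` for empty input.
    """
    if min_markers <= 0 or min_length_bp <= 0 or max_gap_bp <= 0:
        raise ValueError("thresholds must be positive")
    if max_het_in_run < 0:
        raise ValueError("max_het_in_run must be >= 0")
    genotypes = list(genotypes)
    if not genotypes:
        return []
    _check_sorted(genotypes)

    regions: list[AOHRegion] = []
    for chrom, group in groupby(genotypes, key=lambda g: g.chrom):
        # Missing genotypes are dropped up front: neutral everywhere.
        markers = [g for g in group if g.zygosity != "missing"]
        n = len(markers)
        i = 0
        while i < n:
            if markers[i].zygosity != "hom":
                i += 1
                continue
            # Maximal extension from i under the het and gap budgets.
            j = i
            hets = 0
            first_het = -1
            while j + 1 < n:
                if markers[j + 1].pos - markers[j].pos > max_gap_bp:
                    break
                if markers[j + 1].zygosity == "het":
                    if hets + 1 > max_het_in_run:
                        break
                    hets += 1
                    if first_het < 0:
                        first_het = j + 1
                j += 1
            # Runs end on a homozygous marker.
            while markers[j].zygosity == "het":
                j -= 1
            n_markers = j - i + 1
            length = markers[j].pos - markers[i].pos
            if n_markers >= min_markers and length >= min_length_bp:
                regions.append(
                    AOHRegion(
                        chrom=chrom,
                        start=markers[i].pos,
                        stop=markers[j].pos,
                        n_markers=n_markers,
                    )
                )
                i = j + 1
            elif first_het < 0 or first_het > j:
                # No het inside the failed extension: every sub-run is
                # shorter and sparser, so skip past it entirely.
                i = j + 1
            else:
                # Restarting before the first het cannot change the
                # extension endpoint or rescue the thresholds; restart after.
                i = first_het + 1
    return regions


def summarize_aoh(
    regions: Iterable[AOHRegion], genes: Iterable[GeneModel]
) -> list[AOHRegion]:
    """Attach overlapping-gene counts to each region.

    Overlap is half-open on both sides: a gene beginning exactly at
    ``region.stop`` is not counted.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.stop, gene.gene_id
        )
    out: list[AOHRegion] = []
    for region in regions:
        tree = trees.get(region.chrom)
        count = 0
        if tree is not None and region.stop > region.start:
            count = len(tree.overlap(region.start, region.stop))
        out.append(
            AOHRegion(
                chrom=region.chrom,
                start=region.start,
                stop=region.stop,
                n_markers=region.n_markers,
                genes_in_region=count,
            )
        )
    return out
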