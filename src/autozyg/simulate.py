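"""Synthetic consanguineous-proband generator.

This module fabricates a complete desk-scale study of a recessive disorder in
the offspring of first cousins: a toy genome with gene models, autozygous
blocks whose genomic share matches the proband's inbreeding coefficient
(F = 1/16 for first-cousin parents), SNP-array genotypes that are homozygous
inside those blocks, a planted set of coding and noncoding variants with
mock dbSNP / 1000 Genomes membership, one causal homozygous missense variant
buried inside an autozygous block, and Poisson-depth read pileups over every
planted site.  Every operation is deterministic given its seed, and the
returned truth objects drive all downstream recovery tests.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from autozyg.reference import ReferenceGenome
from autozyg.types import (
    BASES,
    AOHRegion,
    GeneModel,
    GenomeSketch,
    GenotypeRecord,
    PileupColumn,
    PlantedVariant,
    TruthSet,
    complement,
)

DEFAULT_QUALITY_MODEL = {"q_high": 30, "q_low": 10, "p_low": 0.15}


class AutozygosityWarning(UserWarning):
    """Raised (as a warning) when requested blocks cannot be placed."""


def make_toy_sketch(
    seed: int = 0,
    n_chromosomes: int = 4,
    chromosome_length_bp: int = 50_000_000,
    n_genes: int = 1200,
    exons_per_gene: tuple[int, int] = (2, 4),
    exon_bp: tuple[int, int] = (120, 240),
    intron_bp: tuple[int, int] = (500, 2000),
) -> GenomeSketch:
    """Build a reduced-scale genome: 4 x 50 Mb chromosomes, ~1 gene / 170 kb.

    Gene density mirrors the human genome's roughly one gene per 150 kb, so
    autozygous blocks of realistic size always contain genes.  Each gene has
    a handful of fully coding exons with total length a multiple of 3.
    """
    rng = np.random.default_rng(seed)
    chroms = tuple(
        (f"chr{i + 1}", chromosome_length_bp) for i in range(n_chromosomes)
    )
    used: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in chroms}
    genes: list[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 50:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))][0]
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exon_lengths = [
            int(rng.integers(exon_bp[0], exon_bp[1] + 1)) for _ in range(n_exons)
        ]
        # Pad the last exon so the CDS is a whole number of codons.
        exon_lengths[-1] += (-sum(exon_lengths)) % 3
        introns = [
            int(rng.integers(intron_bp[0], intron_bp[1] + 1))
            for _ in range(n_exons - 1)
        ]
        span = sum(exon_lengths) + sum(introns)
        start = int(rng.integers(1, chromosome_length_bp - span))
        stop = start + span - 1
        if any(s <= stop and start <= e for s, e in used[chrom]):
            continue
        exons = []
        cursor = start
        for k, length in enumerate(exon_lengths):
            exons.append((cursor, cursor + length - 1))
            cursor += length + (introns[k] if k < n_exons - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{len(genes):04d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=start,
                cds_stop=stop,
            )
        )
        used[chrom].append((start, stop))
    genes.sort(key=lambda g: (g.chrom, g.start))
    reference = ReferenceGenome(seed=int(rng.integers(2**31)))
    return GenomeSketch(chromosomes=chroms, genes=tuple(genes), reference=reference)


def simulate_autozygosity(
    sketch: GenomeSketch,
    inbreeding_coefficient: float = 1 / 16,
    min_block_bp: int = 4_000_000,
    seed: int = 0,
    mean_block_bp: int = 10_000_000,
) -> list[AOHRegion]:
    """Place non-overlapping autozygous blocks covering ~F of the genome.

    Block lengths are exponential with mean ``mean_block_bp``, truncated
    below at ``min_block_bp`` — multi-megabase blocks, the scale produced by
    a recent consanguineous loop.  The last block is trimmed or rounded so
    the total autozygous length lands within half a minimum block of the
    target ``F * genome_length``; placement is uniform with rejection of
    overlaps.

    Emits an :class:`AutozygosityWarning` and returns an empty list when no
    block of the minimum size fits on any chromosome.
    """
    if not (0 < inbreeding_coefficient < 1):
        raise ValueError("inbreeding coefficient must lie in (0, 1)")
    if min_block_bp <= 0:
        raise ValueError("min_block_bp must be positive")
    rng = np.random.default_rng(seed)
    if all(length < min_block_bp for _, length in sketch.chromosomes):
        warnings.warn(
            "no chromosome can host a block of the minimum size; "
            "returning zero blocks",
            AutozygosityWarning,
        )
        return []
    target = inbreeding_coefficient * sketch.total_length
    placed: dict[str, list[tuple[int, int]]] = {
        name: [] for name, _ in sketch.chromosomes
    }
    total = 0
    attempts = 0
    chrom_names = [name for name, _ in sketch.chromosomes]
    chrom_lengths = np.array([length for _, length in sketch.chromosomes], float)
    weights = chrom_lengths / chrom_lengths.sum()
    # Place until the deficit is below half a minimum block: the final
    # block is rounded to min_block_bp, bounding |total - target| by
    # min_block_bp / 2.
    while target - total >= min_block_bp / 2 and attempts < 10_000:
        attempts += 1
        idx = int(rng.choice(len(chrom_names), p=weights))
        chrom = chrom_names[idx]
        chrom_len = int(chrom_lengths[idx])
        length = int(min_block_bp + rng.exponential(mean_block_bp - min_block_bp))
        length = min(length, chrom_len - 1, max(int(target - total), min_block_bp))
        if length < min_block_bp:
            continue
        start = int(rng.integers(1, chrom_len - length + 1))
        stop = start + length
        if any(start < e and s < stop for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, stop))
        total += length
    blocks = [
        AOHRegion(chrom=chrom, start=s, stop=e)
        for chrom in chrom_names
        for s, e in sorted(placed[chrom])
    ]
    if not blocks:
        warnings.warn(
            "block placement failed after rejection limit", AutozygosityWarning
        )
    return blocks


def _in_block(blocks_by_chrom: dict[str, tuple[list[int], list[int]]], chrom: str, pos: int) -> bool:
    if chrom not in blocks_by_chrom:
        return False
    starts, stops = blocks_by_chrom[chrom]
    i = bisect_right(starts, pos) - 1
    return i >= 0 and pos < stops[i]


def _index_blocks(blocks: Iterable[AOHRegion]) -> dict[str, tuple[list[int], list[int]]]:
    by_chrom: dict[str, list[AOHRegion]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = {}
    for chrom, bs in by_chrom.items():
        bs.sort(key=lambda b: b.start)
        out[chrom] = ([b.start for b in bs], [b.stop for b in bs])
    return out


def simulate_snp_genotypes(
    sketch: GenomeSketch,
    blocks: Sequence[AOHRegion],
    marker_spacing_bp: int = 10_000,
    background_het_rate: float = 0.35,
    genotyping_error_rate: float = 0.0005,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> list[GenotypeRecord]:
    """Simulate a genome-wide SNP-array genotype table.

    Markers sit on a regular grid with +/- spacing/4 jitter.  Inside an
    autozygous block every marker is homozygous except for genotyping errors
    (reported het at rate ``genotyping_error_rate``); outside, a marker is
    heterozygous with probability ``background_het_rate`` — the typical het
    rate of polymorphic array content — and homozygous otherwise.
    """
    if marker_spacing_bp <= 0:
        raise ValueError("marker spacing must be positive")
    for rate in (background_het_rate, genotyping_error_rate, missing_rate):
        if not (0 <= rate < 1):
            raise ValueError("rates must lie in [0, 1)")
    if all(length < marker_spacing_bp for _, length in sketch.chromosomes):
        raise ValueError("marker spacing exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    block_index = _index_blocks(blocks)
    records: list[GenotypeRecord] = []
    jitter_span = max(1, marker_spacing_bp // 4)
    for chrom, chrom_len in sketch.chromosomes:
        n = chrom_len // marker_spacing_bp
        if n == 0:
            continue
        grid = (np.arange(1, n + 1) * marker_spacing_bp).astype(np.int64)
        jitter = rng.integers(-jitter_span, jitter_span + 1, size=n)
        positions = np.clip(grid + jitter, 1, chrom_len)
        positions = np.unique(positions)
        u_missing = rng.random(len(positions))
        u_state = rng.random(len(positions))
        for k, pos in enumerate(positions):
            pos = int(pos)
            if u_missing[k] < missing_rate:
                zyg = "missing"
            elif _in_block(block_index, chrom, pos):
                zyg = "het" if u_state[k] < genotyping_error_rate else "hom"
            else:
                zyg = "het" if u_state[k] < background_het_rate else "hom"
            records.append(
                GenotypeRecord(
                    marker_id=f"m_{chrom}_{k:06d}",
                    chrom=chrom,
                    pos=pos,
                    zygosity=zyg,
                )
            )
    return records


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _propose_coding_change(
    gene: GeneModel,
    reference: ReferenceGenome,
    rng: np.random.Generator,
    kind: str,
    used: set[tuple[str, int]],
    max_tries: int = 60,
) -> Optional[tuple[int, str, str]]:
    """Find (genomic pos, ref, alt) in this gene producing the wanted class."""
    positions = gene.cds_genomic_positions()
    n_codons = len(positions) // 3
    for _ in range(max_tries):
        codon_number = int(rng.integers(n_codons))
        codon_pos = positions[codon_number * 3 : codon_number * 3 + 3]
        if gene.strand == "+":
            ref_codon = "".join(reference.base(gene.chrom, p) for p in codon_pos)
        else:
            ref_codon = "".join(
                complement(reference.base(gene.chrom, p)) for p in codon_pos
            )
        ref_aa = _translate(ref_codon)
        if ref_aa == "*":
            continue
        offsets = list(rng.permutation(3))
        for offset in offsets:
            genomic_pos = codon_pos[offset]
            if (gene.chrom, genomic_pos) in used:
                continue
            alts = [b for b in BASES if b != ref_codon[offset]]
            rng.shuffle(alts)
            for alt in alts:
                alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
                alt_aa = _translate(alt_codon)
                if kind == "coding_missense":
                    ok = alt_aa not in (ref_aa, "*")
                elif kind == "coding_synonymous":
                    ok = alt_aa == ref_aa
                elif kind == "coding_nonsense":
                    ok = alt_aa == "*"
                else:
                    raise ValueError(f"unknown coding class {kind!r}")
                if ok:
                    if gene.strand == "+":
                        return genomic_pos, ref_codon[offset], alt
                    return genomic_pos, complement(ref_codon[offset]), complement(alt)
    return None


def plant_variants(
    sketch: GenomeSketch,
    blocks: Sequence[AOHRegion],
    counts_by_class: dict[str, int],
    db_membership_rates: dict[str, float],
    seed: int = 0,
    flank_n: int = 51,
    marker_spacing_bp: int = 10_000,
    kg_rate_scale: float = 0.85,
    hom_fraction: float = 0.5,
) -> TruthSet:
    """Plant a variant set with known truth, including one causal variant.

    ``counts_by_class`` must cover at least ``coding_missense`` (>= 1, since
    the causal homozygous missense variant is one of them),
    ``coding_synonymous`` and ``noncoding``; ``coding_nonsense`` is optional.
    Database membership (mock dbSNP / mock 1000 Genomes) is drawn per class
    at ``db_membership_rates[class]`` (the 1000 Genomes rate scaled by
    ``kg_rate_scale``); the causal variant is absent from both.

    The causal variant is placed in a gene lying at least
    ``flank_n * marker_spacing_bp`` inside an autozygous block, so that the
    expected number of homozygous array markers on each side exceeds
    ``flank_n``; raises ``ValueError`` when no block can host it.
    """
    for key in ("coding_missense", "coding_synonymous", "noncoding"):
        if key not in counts_by_class:
            raise ValueError(f"counts_by_class must define {key!r}")
    if counts_by_class["coding_missense"] < 1:
        raise ValueError(
            "at least one coding_missense variant is required (the causal one)"
        )
    rng = np.random.default_rng(seed)
    block_index = _index_blocks(blocks)
    used: set[tuple[str, int]] = set()
    planted: list[PlantedVariant] = []

    # --- causal variant: a gene buried deep inside an autozygous block ---
    margin = flank_n * marker_spacing_bp
    host_genes = [
        g
        for g in sketch.genes
        for b in blocks
        if b.chrom == g.chrom
        and g.start - b.start >= margin
        and b.stop - g.stop >= margin
    ]
    if not host_genes:
        raise ValueError(
            "no autozygous block is large enough to host the causal variant "
            f"with a {margin} bp homozygous flank on each side"
        )
    causal_gene = host_genes[int(rng.integers(len(host_genes)))]
    proposal = _propose_coding_change(
        causal_gene, sketch.reference, rng, "coding_missense", used
    )
    if proposal is None:
        raise ValueError("could not construct a missense change in the host gene")
    pos, ref, alt = proposal
    used.add((causal_gene.chrom, pos))
    planted.append(
        PlantedVariant(
            chrom=causal_gene.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            zygosity="hom",
            consequence="missense",
            gene_id=causal_gene.gene_id,
            in_dbsnp=False,
            in_kg=False,
            is_causal=True,
        )
    )

    consequence_of = {
        "coding_missense": "missense",
        "coding_synonymous": "synonymous",
        "coding_nonsense": "nonsense",
    }
    gene_spans: dict[str, tuple[list[int], list[int]]] = {}
    for g in sketch.genes:
        gene_spans.setdefault(g.chrom, ([], []))
        gene_spans[g.chrom][0].append(g.start)
        gene_spans[g.chrom][1].append(g.stop)

    def in_any_gene(chrom: str, pos: int) -> bool:
        if chrom not in gene_spans:
            return False
        starts, stops = gene_spans[chrom]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < stops[i]

    for klass, count in counts_by_class.items():
        if klass not in consequence_of and klass != "noncoding":
            raise ValueError(f"unknown variant class {klass!r}")
        remaining = count - 1 if klass == "coding_missense" else count
        rate = float(db_membership_rates.get(klass, 0.0))
        placed = 0
        guard = 0
        while placed < remaining and guard < remaining * 200 + 1000:
            guard += 1
            if klass == "noncoding":
                chrom, chrom_len = sketch.chromosomes[
                    int(rng.integers(len(sketch.chromosomes)))
                ]
                pos = int(rng.integers(1, chrom_len + 1))
                if in_any_gene(chrom, pos) or (chrom, pos) in used:
                    continue
                ref = sketch.reference.base(chrom, pos)
                alt_choices = [b for b in BASES if b != ref]
                alt = alt_choices[int(rng.integers(3))]
                gene_id = None
                consequence = "noncoding"
            else:
                gene = sketch.genes[int(rng.integers(len(sketch.genes)))]
                proposal = _propose_coding_change(
                    gene, sketch.reference, rng, klass, used, max_tries=8
                )
                if proposal is None:
                    continue
                chrom = gene.chrom
                pos, ref, alt = proposal
                gene_id = gene.gene_id
                consequence = consequence_of[klass]
            used.add((chrom, pos))
            in_dbsnp = bool(rng.random() < rate)
            in_kg = bool(rng.random() < rate * kg_rate_scale)
            zygosity = "hom" if rng.random() < hom_fraction else "het"
            planted.append(
                PlantedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    zygosity=zygosity,
                    consequence=consequence,
                    gene_id=gene_id,
                    in_dbsnp=in_dbsnp,
                    in_kg=in_kg,
                )
            )
            placed += 1
        if placed < remaining:
            raise ValueError(
                f"could only place {placed}/{remaining} variants of class {klass}"
            )
    planted.sort(key=lambda v: (v.chrom, v.pos))
    return TruthSet(aoh_blocks=tuple(blocks), planted_variants=tuple(planted))


def simulate_pileups(
    truth: TruthSet,
    sketch: GenomeSketch,
    mean_depth: float = 56.0,
    base_error_rate: float = 0.01,
    quality_model: Optional[dict] = None,
    seed: int = 0,
    n_reference_positions: int = 500,
) -> list[PileupColumn]:
    """Simulate per-position pileups over planted sites plus reference sites.

    Depth is Poisson with mean ``mean_depth`` (the study-scale default of 56x
    target coverage).  Each read carries the true allele — the alternate at
    homozygous-alt sites, a fair coin at heterozygous sites — then suffers a
    uniform substitution error with probability ``base_error_rate`` and is
    assigned a low base quality with probability ``quality_model['p_low']``,
    landing it in the low-quality counts that the caller ignores.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if not (0 <= base_error_rate < 0.5):
        raise ValueError("base error rate must lie in [0, 0.5)")
    qm = dict(DEFAULT_QUALITY_MODEL)
    if quality_model:
        qm.update(quality_model)
    p_low = float(qm["p_low"])
    rng = np.random.default_rng(seed)

    targets: list[tuple[str, int, str, str, Optional[str]]] = []
    used = {(v.chrom, v.pos) for v in truth.planted_variants}
    for v in truth.planted_variants:
        targets.append((v.chrom, v.pos, v.ref, v.zygosity, v.alt))
    # Reference (non-variant) positions inside genes: coverage summary fodder.
    guard = 0
    placed = 0
    while sketch.genes and placed < n_reference_positions and guard < n_reference_positions * 50 + 100:
        guard += 1
        gene = sketch.genes[int(rng.integers(len(sketch.genes)))]
        positions = gene.cds_genomic_positions()
        pos = int(positions[int(rng.integers(len(positions)))])
        if (gene.chrom, pos) in used:
            continue
        used.add((gene.chrom, pos))
        targets.append(
            (gene.chrom, pos, sketch.reference.base(gene.chrom, pos), "ref", None)
        )
        placed += 1
    targets.sort(key=lambda t: (t[0], t[1]))

    base_idx = {b: i for i, b in enumerate(BASES)}
    columns: list[PileupColumn] = []
    for chrom, pos, ref, zygosity, alt in targets:
        depth = int(rng.poisson(mean_depth))
        probs = np.zeros(4)
        if zygosity == "hom":
            true_probs = {alt: 1.0}
        elif zygosity == "het":
            true_probs = {ref: 0.5, alt: 0.5}
        else:
            true_probs = {ref: 1.0}
        for base, p in true_probs.items():
            probs[base_idx[base]] += p * (1 - base_error_rate)
            for other in BASES:
                if other != base:
                    probs[base_idx[other]] += p * base_error_rate / 3
        counts = rng.multinomial(depth, probs)
        hi = rng.binomial(counts, 1 - p_low)
        lo = counts - hi
        columns.append(
            PileupColumn(
                chrom=chrom,
                pos=pos,
                ref=ref,
                counts_hi={b: int(hi[i]) for i, b in enumerate(BASES) if hi[i]},
                counts_lo={b: int(lo[i]) for i, b in enumerate(BASES) if lo[i]},
            )
        )
    return columns
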