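"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
Marker and variant positions are 1-based, as on genotyping arrays and in VCF.
Region intervals are half-open ``[start, stop)`` for all overlap logic, so
``length == stop - start``.  Gene exons are stored as 1-based inclusive
``(start, stop)`` pairs, the convention of RefSeq-style gene tables; helpers on
:class:`GeneModel` do the conversion where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

Zygosity = Literal["hom", "het", "missing"]
CallZygosity = Literal["hom", "het"]
Consequence = Literal["missense", "synonymous", "nonsense", "noncoding"]

BASES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


@dataclass(frozen=True)
class GenotypeRecord:
    """One SNP-array marker call."""

    marker_id: str
    chrom: str
    pos: int
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker position must be >= 1, got {self.pos}")
        if self.zygosity not in ("hom", "het", "missing"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class AOHRegion:
    """A run of homozygosity: half-open interval [start, stop).

    ``n_markers`` is the number of informative (non-missing) array markers
    supporting the run; simulated truth blocks, which are defined in base-pair
    space before markers exist, carry ``n_markers=None``.
    """

    chrom: str
    start: int
    stop: int
    n_markers: Optional[int] = None
    genes_in_region: Optional[int] = None

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(
                f"region stop {self.stop} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership test: start <= pos < stop."""
        return self.start <= pos < self.stop


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base counts, split at the base-quality cutoff.

    ``counts_hi`` holds bases at or above the cutoff (these alone drive
    calling); ``counts_lo`` holds the rest and is never used for genotype
    decisions.
    """

    chrom: str
    pos: int
    ref: str
    counts_hi: dict[str, int] = field(default_factory=dict)
    counts_lo: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValueError(f"reference base must be one of ACGT, got {self.ref!r}")
        for counts in (self.counts_hi, self.counts_lo):
            for base, n in counts.items():
                if base not in BASES:
                    raise ValueError(f"bad base {base!r} in pileup column")
                if n < 0:
                    raise ValueError("negative base count")


@dataclass(frozen=True)
class VariantCall:
    """A called single-nucleotide variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: CallZygosity
    depth_hq: int
    alt_fraction: float
    call_rate_percent: int

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt allele equals reference")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError("ref/alt must be single bases")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: exons plus a CDS span.

    ``exons`` are sorted, non-overlapping, 1-based inclusive intervals.
    ``cds_start``/``cds_stop`` (1-based inclusive, genomic orientation) bound
    the translated portion; the coding length must be a multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_stop: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_stop = 0
        for start, stop in self.exons:
            if start <= prev_stop:
                raise ValueError(
                    f"exons of {self.gene_id} overlap or are unsorted"
                )
            if stop < start:
                raise ValueError(f"exon stop < start in {self.gene_id}")
            prev_stop = stop
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.cds_stop < self.cds_start:
            raise ValueError(f"CDS stop < start in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def stop(self) -> int:
        """Exclusive stop of the gene span (half-open convention)."""
        return self.exons[-1][1] + 1

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of coding bases, in 5'->3' order of the mRNA.

        For minus-strand genes the list runs from ``cds_stop`` downward.
        Raises ``ValueError`` if the coding length is not a multiple of 3.
        """
        positions: list[int] = []
        for start, stop in self.exons:
            lo = max(start, self.cds_start)
            hi = min(stop, self.cds_stop)
            if lo <= hi:
                positions.extend(range(lo, hi + 1))
        if not positions or len(positions) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {len(positions)} "
                "is not a positive multiple of 3"
            )
        if self.strand == "-":
            positions.reverse()
        return positions


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call plus coding consequence and database membership."""

    call: VariantCall
    consequence: Consequence
    gene_id: Optional[str] = None
    aa_change: Optional[str] = None
    in_dbsnp: bool = False
    in_kg: bool = False

    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def pos(self) -> int:
        return self.call.pos

    @property
    def zygosity(self) -> str:
        return self.call.zygosity


@dataclass(frozen=True)
class CascadeReport:
    """Ordered filter steps with surviving-variant counts."""

    steps: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        prev = None
        for name, count in self.steps:
            if count < 0:
                raise ValueError("negative survivor count")
            if prev is not None and count > prev:
                raise ValueError(
                    f"cascade step {name!r} increased the survivor count"
                )
            prev = count

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.steps)

    def count_after(self, step_name: str) -> int:
        for name, count in self.steps:
            if name == step_name:
                return count
        raise KeyError(step_name)


@dataclass(frozen=True)
class PlantedVariant:
    """Ground-truth record for one simulated variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: CallZygosity
    consequence: Consequence
    gene_id: Optional[str]
    in_dbsnp: bool
    in_kg: bool
    is_causal: bool = False


@dataclass
class GenomeSketch:
    """A toy genome: chromosome sizes, gene models, and a reference accessor."""

    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneModel, ...]
    reference: "object" = None  # ReferenceGenome; untyped to avoid an import cycle

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome sketch has no chromosomes")
        sizes = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for gene in self.genes:
            if gene.chrom not in sizes:
                raise ValueError(f"gene {gene.gene_id} on unknown chromosome")
            if gene.stop - 1 > sizes[gene.chrom] or gene.start < 1:
                raise ValueError(
                    f"gene {gene.gene_id} extends beyond its chromosome"
                )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(name)


@dataclass
class TruthSet:
    """Everything the simulator planted, for downstream truth comparison."""

    aoh_blocks: tuple[AOHRegion, ...]
    planted_variants: tuple[PlantedVariant, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for v in self.planted_variants:
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate planted position {key}")
            seen.add(key)
        causal = [v for v in self.planted_variants if v.is_causal]
        if len(causal) > 1:
            raise ValueError("more than one causal variant planted")

    @property
    def causal_variant(self) -> Optional[PlantedVariant]:
        for v in self.planted_variants:
            if v.is_causal:
                return v
        return None

    def dbsnp_keys(self) -> set[tuple[str, int, str, str]]:
        return {
            (v.chrom, v.pos, v.ref, v.alt)
            for v in self.planted_variants
            if v.in_dbsnp
        }

    def kg_keys(self) -> set[tuple[str, int, str, str]]:
        return {
            (v.chrom, v.pos, v.ref, v.alt)
            for v in self.planted_variants
            if v.in_kg
        }
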