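"""Reference fixture from a published consanguineous-proband exome study.

These constants reproduce the published inputs of a homozygosity-mapping
study of a heterotaxy proband (sample LAT1180) born to first-cousin parents:
the SNP-array AOH intervals, the four candidate variant coordinates that
mapped into them, the read pileup supporting the causal *SHROOM3*-like
p.G60V call (89 high-quality reads with T versus 1 with C), the rare-variant
screening rows, and a small synthetic six-species protein alignment standing
in for the published cross-species conservation panel around glycine 60.

They let the interval-intersection, calling and reporting layers be checked
against printed study values without any external download.
"""

from __future__ import annotations

from autozyg.types import AOHRegion, PileupColumn

#: Major absence-of-heterozygosity regions detected on the proband's SNP
#: array (chrom, start bp, stop bp, number of markers).  The two chr4 rows
#: are carried as printed; note their printed lengths are not reproducible
#: as stop - start, so length-convention checks use the other rows.
AOH_REGIONS: tuple[AOHRegion, ...] = (
    AOHRegion("1", 186_823_646, 192_715_568, n_markers=1_533),
    AOHRegion("4", 69_717_060, 89_279_933, n_markers=8_000),
    AOHRegion("4", 146_672_223, 182_010_642, n_markers=8_626),
    AOHRegion("7", 40_952_323, 47_059_534, n_markers=2_324),
    AOHRegion("13", 40_907_456, 47_064_783, n_markers=2_461),
    AOHRegion("15", 46_957_310, 51_984_619, n_markers=1_792),
    AOHRegion("18", 22_763_465, 33_898_685, n_markers=4_107),
)

#: AOH rows whose printed length equals stop - start exactly; used to pin
#: the length convention.
SELF_CONSISTENT_LENGTHS: tuple[tuple[str, int, int, int], ...] = (
    ("1", 186_823_646, 192_715_568, 5_891_922),
    ("7", 40_952_323, 47_059_534, 6_107_211),
    ("13", 40_907_456, 47_064_783, 6_157_327),
    ("15", 46_957_310, 51_984_619, 5_027_309),
    ("18", 22_763_465, 33_898_685, 11_135_220),
)

#: The four homozygous missense candidates that mapped into the AOH regions:
#: (gene, protein change, chrom, position).
CANDIDATE_VARIANTS: tuple[tuple[str, str, str, int], ...] = (
    ("CXCL2", "p.T39A", "4", 74_964_625),
    ("SHROOM3", "p.G60V", "4", 77_476_772),
    ("CTSO", "p.Q122E", "4", 156_863_489),
    ("RXFP1", "p.T235I", "4", 159_538_306),
)

#: Read pileup at the causal site: 89 high-quality T reads versus 1 C on a
#: reference C column — a 99% per-site call rate, called homozygous.
CAUSAL_PILEUP = PileupColumn(
    chrom="4",
    pos=77_476_772,
    ref="C",
    counts_hi={"T": 89, "C": 1},
    counts_lo={},
)

#: Rare-variant screening rows: (sample, protein change, zygosity, chrom, pos).
SCREENING_ROWS: tuple[tuple[str, str, str, str, int], ...] = (
    ("LAT0820", "p.E1775K", "hom", "4", 77_680_822),
    ("LAT0844", "p.P173H", "het", "4", 77_652_019),
    ("LAT0982", "p.G1864D", "het", "4", 77_692_019),
    ("LAT0990", "p.D537N", "hom", "4", 77_660_935),
    ("LAT1180", "p.G60V", "hom", "4", 77_476_772),
)

#: Synthetic six-species protein alignment window around the mutated glycine
#: (column index 5 in this window).  The residue identities away from the
#: invariant column are fabricated; only the invariant-G column matters.
GLY60_COLUMN_INDEX = 5
GLY60_ALIGNMENT: tuple[tuple[str, str], ...] = (
    ("human", "SLRTPGSKPVQ"),
    ("chimp", "SLRTPGSKPVQ"),
    ("mouse", "SLRSPGSKPLQ"),
    ("rat", "SLRSPGSKPLQ"),
    ("chicken", "ALKTPGAKPVQ"),
    ("zebrafish", "ALKSPGAKSIQ"),
)

#: Headline exome-filter totals from the published cascade; used to check
#: the complement arithmetic |input| - |known| = |survivors|.
PUBLISHED_TOTAL_VARIANTS = 70_812
PUBLISHED_DBSNP_MEMBERS = 63_728
PUBLISHED_NOT_IN_DBSNP = 7_084
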