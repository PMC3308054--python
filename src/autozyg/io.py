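"""Readers and writers for the pipeline's on-disk formats.

All tabular artifacts are headered TSV (read and written with pandas).
AOH regions additionally go out as BED — 0-based half-open, converted from
the 1-based marker coordinates by ``start - 1``.  Variant calls are written
as VCF 4.2 with ``DPHQ`` (high-quality depth) and ``AFRAC`` (alternate
allele fraction) INFO keys and a single-sample ``GT`` column, and read back
with cyvcf2.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from cyvcf2 import VCF

from autozyg.calling import CoverageSummary
from autozyg.types import (
    AnnotatedVariant,
    AOHRegion,
    CascadeReport,
    GenotypeRecord,
    PileupColumn,
    PlantedVariant,
    TruthSet,
    VariantCall,
    BASES,
)

# ---------------------------------------------------------------- genotypes


def write_genotypes(records: Iterable[GenotypeRecord], path: str) -> None:
    df = pd.DataFrame(
        [(g.marker_id, g.chrom, g.pos, g.zygosity) for g in records],
        columns=["marker_id", "chrom", "pos", "zygosity"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str) -> list[GenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GenotypeRecord(
            marker_id=str(r.marker_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            zygosity=str(r.zygosity),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ pileups

_PILEUP_COLUMNS = (
    ["chrom", "pos", "ref"]
    + [f"count{b}_hi" for b in BASES]
    + [f"count{b}_lo" for b in BASES]
)


def write_pileups(columns: Iterable[PileupColumn], path: str) -> None:
    rows = []
    for c in columns:
        rows.append(
            [c.chrom, c.pos, c.ref]
            + [c.counts_hi.get(b, 0) for b in BASES]
            + [c.counts_lo.get(b, 0) for b in BASES]
        )
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileups(path: str) -> list[PileupColumn]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        hi = {b: int(getattr(r, f"count{b}_hi")) for b in BASES}
        lo = {b: int(getattr(r, f"count{b}_lo")) for b in BASES}
        out.append(
            PileupColumn(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                counts_hi={b: n for b, n in hi.items() if n},
                counts_lo={b: n for b, n in lo.items() if n},
            )
        )
    return out


# ------------------------------------------------------------------ regions


def write_regions(regions: Iterable[AOHRegion], path: str) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.start, r.stop, r.length, r.n_markers, r.genes_in_region)
            for r in regions
        ],
        columns=["chrom", "start", "stop", "length", "n_markers", "genes_in_region"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: str) -> list[AOHRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})

    def opt(v) -> Optional[int]:
        return None if pd.isna(v) else int(v)

    return [
        AOHRegion(
            chrom=str(r.chrom),
            start=int(r.start),
            stop=int(r.stop),
            n_markers=opt(r.n_markers),
            genes_in_region=opt(r.genes_in_region),
        )
        for r in df.itertuples()
    ]


def write_regions_bed(regions: Iterable[AOHRegion], path: str) -> None:
    """BED output: 0-based half-open, start = 1-based marker start - 1."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"AOH_{r.chrom}_{r.start}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.stop - 1}\t{name}\n")


# -------------------------------------------------------------------- truth


def write_truth(truth: TruthSet, variants_path: str, blocks_bed_path: str) -> None:
    df = pd.DataFrame(
        [
            (
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
                v.zygosity,
                v.consequence,
                v.gene_id or "",
                int(v.in_dbsnp),
                int(v.in_kg),
                int(v.is_causal),
            )
            for v in truth.planted_variants
        ],
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "zygosity",
            "consequence",
            "gene_id",
            "in_dbsnp",
            "in_kg",
            "is_causal",
        ],
    )
    df.to_csv(variants_path, sep="\t", index=False)
    with open(blocks_bed_path, "w") as fh:
        for b in truth.aoh_blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.stop - 1}\ttruth_block\n")


def read_truth_variants(path: str) -> list[PlantedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return [
        PlantedVariant(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            zygosity=str(r.zygosity),
            consequence=str(r.consequence),
            gene_id=str(r.gene_id) or None,
            in_dbsnp=bool(int(r.in_dbsnp)),
            in_kg=bool(int(r.in_kg)),
            is_causal=bool(int(r.is_causal)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- databases


def write_database(keys: Iterable[tuple[str, int, str, str]], path: str) -> None:
    """Mock known-variant catalog: TSV of (chrom, pos, ref, alt)."""
    df = pd.DataFrame(sorted(keys), columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)


def read_database(path: str) -> set[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples()
    }


# ---------------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=autozyg
##INFO=<ID=DPHQ,Number=1,Type=Integer,Description="High-quality read depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="High-quality alternate base count">
##INFO=<ID=AFRAC,Number=1,Type=Float,Description="Alternate allele fraction of high-quality bases">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPROBAND
"""


def write_vcf(calls: Sequence[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            gt = "1/1" if c.zygosity == "hom" else "0/1"
            ac = round(c.alt_fraction * c.depth_hq)
            info = f"DPHQ={c.depth_hq};AC={ac};AFRAC={c.alt_fraction:.6f}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def read_vcf(path: str) -> list[VariantCall]:
    from autozyg.calling import allele_fraction_percent

    calls = []
    for rec in VCF(path):
        depth = int(rec.INFO["DPHQ"])
        alt_count = int(rec.INFO["AC"])
        gt = rec.genotypes[0]
        zygosity = "hom" if gt[0] == 1 and gt[1] == 1 else "het"
        calls.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                zygosity=zygosity,
                depth_hq=depth,
                # The integer alternate count reconstructs the fraction
                # exactly; the float AFRAC field is for human readers.
                alt_fraction=alt_count / depth,
                call_rate_percent=allele_fraction_percent(
                    alt_count, depth - alt_count
                ),
            )
        )
    return calls


# ------------------------------------------------------------- reports etc.


def write_coverage_summary(summary: CoverageSummary, path: str) -> None:
    rows = [
        ("Targeted positions", summary.n_positions),
        ("Mean depth of coverage of targets", round(summary.mean_depth, 2)),
        ("Bases covered at depth of >= 1x", f"{summary.frac_ge_1x:.1%}"),
        ("Bases covered at depth of >= 5x", f"{summary.frac_ge_5x:.1%}"),
        ("Bases covered at depth of >= 10x", f"{summary.frac_ge_10x:.1%}"),
    ]
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_cascade_report(report: CascadeReport, path: str) -> None:
    pd.DataFrame(list(report), columns=["step", "surviving_variants"]).to_csv(
        path, sep="\t", index=False
    )


def write_candidates(
    candidates: Sequence[AnnotatedVariant],
    path: str,
    flanking: Optional[dict[tuple[str, int], tuple[int, int, bool]]] = None,
    sample: str = "PROBAND",
) -> None:
    rows = []
    for v in candidates:
        left, right, ok = (None, None, None)
        if flanking is not None:
            left, right, ok = flanking.get((v.chrom, v.pos), (None, None, None))
        rows.append(
            (
                sample,
                v.gene_id or "",
                v.aa_change or "",
                v.zygosity,
                f"{v.chrom}:{v.pos}",
                left,
                right,
                ok,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "sample",
            "gene",
            "aa_change",
            "zygosity",
            "coordinates",
            "hom_flank_left",
            "hom_flank_right",
            "flank_pass",
        ],
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- config


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
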