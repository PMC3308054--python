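"""End-to-end pipeline: simulate, detect AOH, call, annotate, filter, report.

``run_all`` executes the full study emulation from one :class:`RunConfig`
and writes every artifact — genotype table, AOH regions (TSV + BED), VCF,
coverage summary, cascade report, candidate table, truth files and a
truth-comparison file — into an output directory, together with a resolved
copy of the configuration.  All randomness derives from the single top-level
seed; a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from autozyg import io as azio
from autozyg.annotate import annotate_consequence
from autozyg.calling import CoverageSummary, call_all
from autozyg.cascade import (
    DEFAULT_STEPS,
    filter_cascade,
    flanking_hom_support,
)
from autozyg.roh import scan_aoh, summarize_aoh
from autozyg.simulate import (
    make_toy_sketch,
    plant_variants,
    simulate_autozygosity,
    simulate_pileups,
    simulate_snp_genotypes,
)
from autozyg.types import (
    AnnotatedVariant,
    AOHRegion,
    CascadeReport,
    GenotypeRecord,
    TruthSet,
    VariantCall,
)

logger = logging.getLogger("autozyg")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Strict):
    n_chromosomes: int = 4
    chromosome_length_bp: int = 50_000_000
    n_genes: int = 1200


class AutozygosityConfig(_Strict):
    inbreeding_coefficient: float = 1 / 16
    min_block_bp: int = 4_000_000
    mean_block_bp: int = 10_000_000


class MarkerConfig(_Strict):
    spacing_bp: int = 10_000
    background_het_rate: float = 0.35
    genotyping_error_rate: float = 0.0005
    missing_rate: float = 0.0


class VariantConfig(_Strict):
    coding_missense: int = 150
    coding_synonymous: int = 250
    coding_nonsense: int = 10
    noncoding: int = 600
    db_membership_rate: float = 0.9
    noncoding_db_membership_rate: float = 0.95
    kg_rate_scale: float = 0.85
    hom_fraction: float = 0.5
    flank_n: int = 51


class PileupConfig(_Strict):
    mean_depth: float = 56.0
    base_error_rate: float = 0.01
    p_low_quality: float = 0.15
    n_reference_positions: int = 500


class CallingConfig(_Strict):
    min_depth: int = 10
    het_low: float = 0.25
    hom_cut: float = 0.75


class RohConfig(_Strict):
    min_markers: int = 50
    min_length_bp: int = 3_000_000
    max_het_in_run: int = 2
    max_gap_bp: int = 1_000_000


class CascadeConfig(_Strict):
    steps: tuple[str, ...] = DEFAULT_STEPS
    flank_required: int = 51
    flank_mode: str = "per_side"


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    genome: GenomeConfig = GenomeConfig()
    autozygosity: AutozygosityConfig = AutozygosityConfig()
    markers: MarkerConfig = MarkerConfig()
    variants: VariantConfig = VariantConfig()
    pileups: PileupConfig = PileupConfig()
    calling: CallingConfig = CallingConfig()
    roh: RohConfig = RohConfig()
    cascade: CascadeConfig = CascadeConfig()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        return cls.model_validate(azio.load_yaml(path))


@dataclass
class RunBundle:
    """In-memory results of a full pipeline run."""

    config: RunConfig
    truth: TruthSet
    genotypes: list[GenotypeRecord]
    regions: list[AOHRegion]
    calls: list[VariantCall]
    coverage: CoverageSummary
    annotated: list[AnnotatedVariant]
    report: CascadeReport
    candidates: list[AnnotatedVariant]
    flanking: dict = field(default_factory=dict)

    @property
    def causal_recovered(self) -> bool:
        causal = self.truth.causal_variant
        if causal is None:
            return False
        return any(
            v.chrom == causal.chrom and v.pos == causal.pos for v in self.candidates
        )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive per-stage integer seeds from the single run seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def run_all(config: RunConfig, outdir: Optional[str] = None) -> RunBundle:
    """Execute the full pipeline; optionally write the artifact bundle."""
    seeds = _stage_seeds(config.seed)
    logger.info("pipeline seed %d; stage seeds %s", config.seed, seeds)

    sketch = make_toy_sketch(
        seed=seeds[0],
        n_chromosomes=config.genome.n_chromosomes,
        chromosome_length_bp=config.genome.chromosome_length_bp,
        n_genes=config.genome.n_genes,
    )
    blocks = simulate_autozygosity(
        sketch,
        inbreeding_coefficient=config.autozygosity.inbreeding_coefficient,
        min_block_bp=config.autozygosity.min_block_bp,
        mean_block_bp=config.autozygosity.mean_block_bp,
        seed=seeds[1],
    )
    genotypes = simulate_snp_genotypes(
        sketch,
        blocks,
        marker_spacing_bp=config.markers.spacing_bp,
        background_het_rate=config.markers.background_het_rate,
        genotyping_error_rate=config.markers.genotyping_error_rate,
        missing_rate=config.markers.missing_rate,
        seed=seeds[2],
    )
    counts = {
        "coding_missense": config.variants.coding_missense,
        "coding_synonymous": config.variants.coding_synonymous,
        "coding_nonsense": config.variants.coding_nonsense,
        "noncoding": config.variants.noncoding,
    }
    rates = {
        "coding_missense": config.variants.db_membership_rate,
        "coding_synonymous": config.variants.db_membership_rate,
        "coding_nonsense": config.variants.db_membership_rate,
        "noncoding": config.variants.noncoding_db_membership_rate,
    }
    if counts["coding_missense"] + counts["coding_synonymous"] + counts["noncoding"] == 0 and counts["coding_nonsense"] == 0:
        truth = TruthSet(aoh_blocks=tuple(blocks), planted_variants=())
    else:
        truth = plant_variants(
            sketch,
            blocks,
            counts_by_class=counts,
            db_membership_rates=rates,
            seed=seeds[3],
            flank_n=config.variants.flank_n,
            marker_spacing_bp=config.markers.spacing_bp,
            kg_rate_scale=config.variants.kg_rate_scale,
            hom_fraction=config.variants.hom_fraction,
        )
    pileups = simulate_pileups(
        truth,
        sketch,
        mean_depth=config.pileups.mean_depth,
        base_error_rate=config.pileups.base_error_rate,
        quality_model={"p_low": config.pileups.p_low_quality},
        seed=seeds[4],
        n_reference_positions=config.pileups.n_reference_positions,
    )

    logger.info(
        "AOH scan thresholds: min_markers=%d min_length_bp=%d "
        "max_het_in_run=%d max_gap_bp=%d",
        config.roh.min_markers,
        config.roh.min_length_bp,
        config.roh.max_het_in_run,
        config.roh.max_gap_bp,
    )
    regions = scan_aoh(
        genotypes,
        min_markers=config.roh.min_markers,
        min_length_bp=config.roh.min_length_bp,
        max_het_in_run=config.roh.max_het_in_run,
        max_gap_bp=config.roh.max_gap_bp,
    )
    regions = summarize_aoh(regions, sketch.genes)

    logger.info(
        "calling thresholds: min_depth=%d het_low=%.2f hom_cut=%.2f",
        config.calling.min_depth,
        config.calling.het_low,
        config.calling.hom_cut,
    )
    calls, coverage = call_all(
        pileups,
        min_depth=config.calling.min_depth,
        het_low=config.calling.het_low,
        hom_cut=config.calling.hom_cut,
    )

    dbsnp = truth.dbsnp_keys()
    kg = truth.kg_keys()
    annotated = [
        annotate_consequence(
            c,
            sketch.genes,
            sketch.reference,
            in_dbsnp=(c.chrom, c.pos, c.ref, c.alt) in dbsnp,
            in_kg=(c.chrom, c.pos, c.ref, c.alt) in kg,
        )
        for c in calls
    ]

    report, candidates = filter_cascade(
        annotated, regions, steps=config.cascade.steps
    )
    flanking = {
        (v.chrom, v.pos): flanking_hom_support(
            v,
            genotypes,
            required=config.cascade.flank_required,
            mode=config.cascade.flank_mode,
        )
        for v in candidates
    }

    bundle = RunBundle(
        config=config,
        truth=truth,
        genotypes=genotypes,
        regions=regions,
        calls=calls,
        coverage=coverage,
        annotated=annotated,
        report=report,
        candidates=candidates,
        flanking=flanking,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: RunBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    azio.dump_yaml(bundle.config.model_dump(mode="json"), path("config.resolved.yaml"))
    azio.write_genotypes(bundle.genotypes, path("genotypes.tsv"))
    azio.write_regions(bundle.regions, path("aoh_regions.tsv"))
    azio.write_regions_bed(bundle.regions, path("aoh_regions.bed"))
    azio.write_vcf(bundle.calls, path("calls.vcf"))
    azio.write_coverage_summary(bundle.coverage, path("coverage_summary.tsv"))
    azio.write_cascade_report(bundle.report, path("cascade_report.tsv"))
    azio.write_candidates(
        bundle.candidates, path("candidates.tsv"), flanking=bundle.flanking
    )
    azio.write_truth(
        bundle.truth, path("truth_variants.tsv"), path("truth_blocks.bed")
    )
    azio.write_database(bundle.truth.dbsnp_keys(), path("mock_dbsnp.tsv"))
    azio.write_database(bundle.truth.kg_keys(), path("mock_kg.tsv"))
    with open(path("truth_comparison.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        causal = bundle.truth.causal_variant
        fh.write(
            "causal_variant\t%s\n"
            % (f"{causal.chrom}:{causal.pos}" if causal else "none")
        )
        fh.write(f"causal_recovered\t{int(bundle.causal_recovered)}\n")
        fh.write(f"final_candidates\t{len(bundle.candidates)}\n")
        fh.write(f"truth_blocks\t{len(bundle.truth.aoh_blocks)}\n")
        fh.write(f"detected_regions\t{len(bundle.regions)}\n")


def render_reports(bundle: RunBundle) -> dict[str, str]:
    """Fixed-width text renderings of the region, coverage, cascade and
    candidate tables.  Raises ``KeyError`` naming any missing bundle member."""
    for member in ("regions", "coverage", "report", "candidates"):
        if getattr(bundle, member, None) is None:
            raise KeyError(f"bundle member missing: {member}")
    out: dict[str, str] = {}

    region_lines = [
        f"{'chrom':<8}{'start':>12}{'stop':>12}{'length':>12}"
        f"{'markers':>9}{'genes':>7}"
    ]
    for r in bundle.regions:
        region_lines.append(
            f"{r.chrom:<8}{r.start:>12}{r.stop:>12}{r.length:>12}"
            f"{r.n_markers if r.n_markers is not None else '-':>9}"
            f"{r.genes_in_region if r.genes_in_region is not None else '-':>7}"
        )
    out["aoh_regions"] = "\n".join(region_lines)

    c = bundle.coverage
    out["coverage"] = "\n".join(
        [
            f"Targeted positions                      {c.n_positions}",
            f"Mean depth of coverage of targets       {c.mean_depth:.1f}",
            f"Bases covered at depth of >= 1x         {c.frac_ge_1x:.1%}",
            f"Bases covered at depth of >= 5x         {c.frac_ge_5x:.1%}",
            f"Bases covered at depth of >= 10x        {c.frac_ge_10x:.1%}",
        ]
    )

    cascade_lines = [f"{'step':<20}{'surviving':>10}"]
    for name, count in bundle.report:
        cascade_lines.append(f"{name:<20}{count:>10}")
    out["cascade"] = "\n".join(cascade_lines)

    cand_lines = [f"{'gene':<10}{'aa_change':<12}{'zygosity':<10}{'coordinates':<20}"]
    for v in bundle.candidates:
        cand_lines.append(
            f"{v.gene_id or '-':<10}{v.aa_change or '-':<12}"
            f"{v.zygosity:<10}{v.chrom + ':' + str(v.pos):<20}"
        )
    out["candidates"] = "\n".join(cand_lines)
    return out
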