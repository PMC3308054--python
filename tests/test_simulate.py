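"""Synthetic-data generator: inbreeding-coefficient calibration, genotype
composition, variant planting and database-flag conservation, determinism."""

import warnings

import numpy as np
import pytest
from scipy.stats import binom

from autozyg import (
    make_toy_sketch,
    plant_variants,
    simulate_autozygosity,
    simulate_pileups,
    simulate_snp_genotypes,
)
from autozyg.simulate import AutozygosityWarning
from autozyg.types import GenomeSketch


@pytest.fixture(scope="module")
def bare_sketch():
    """A 200 Mb genome without genes, for fast block-placement checks."""
    return make_toy_sketch(seed=0, n_chromosomes=4, n_genes=0)


class TestSimulateAutozygosity:
    def test_total_matches_inbreeding_coefficient(self, bare_sketch):
        """Across 100 seeds, total block length per genome stays within 30%
        of F x genome length (F = 1/16, the first-cousin expectation)."""
        F = 1 / 16
        target = F * bare_sketch.total_length
        for seed in range(100):
            blocks = simulate_autozygosity(bare_sketch, F, 4_000_000, seed=seed)
            total = sum(b.length for b in blocks)
            assert abs(total - target) <= 0.3 * target, seed

    def test_blocks_disjoint_and_min_length(self, bare_sketch):
        blocks = simulate_autozygosity(bare_sketch, 0.2, 4_000_000, seed=5)
        by_chrom = {}
        for b in blocks:
            assert b.length >= 4_000_000
            by_chrom.setdefault(b.chrom, []).append(b)
        for bs in by_chrom.values():
            bs.sort(key=lambda b: b.start)
            for a, b in zip(bs, bs[1:]):
                assert a.stop <= b.start

    def test_same_seed_identical(self, bare_sketch):
        a = simulate_autozygosity(bare_sketch, 1 / 16, 4_000_000, seed=9)
        b = simulate_autozygosity(bare_sketch, 1 / 16, 4_000_000, seed=9)
        assert a == b

    def test_impossible_placement_warns(self):
        sketch = GenomeSketch(chromosomes=(("chr1", 1_000_000),), genes=())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            blocks = simulate_autozygosity(sketch, 0.5, 2_000_000, seed=0)
        assert blocks == []
        assert any(issubclass(w.category, AutozygosityWarning) for w in caught)

    @pytest.mark.parametrize("bad_f", [0.0, 1.0, -0.1, 1.5])
    def test_bad_inbreeding_coefficient(self, bare_sketch, bad_f):
        with pytest.raises(ValueError):
            simulate_autozygosity(bare_sketch, bad_f, 4_000_000, seed=0)


class TestSimulateGenotypes:
    def test_error_free_blocks_all_homozygous(self, bare_sketch):
        blocks = simulate_autozygosity(bare_sketch, 0.2, 4_000_000, seed=1)
        genotypes = simulate_snp_genotypes(
            bare_sketch, blocks, genotyping_error_rate=0.0, seed=1
        )
        in_block = [
            g
            for g in genotypes
            if any(b.chrom == g.chrom and b.contains(g.pos) for b in blocks)
        ]
        assert len(in_block) > 1000
        assert all(g.zygosity == "hom" for g in in_block)

    def test_zero_background_het_rate_all_homozygous(self, bare_sketch):
        genotypes = simulate_snp_genotypes(
            bare_sketch, [], background_het_rate=0.0,
            genotyping_error_rate=0.0, seed=2,
        )
        assert all(g.zygosity == "hom" for g in genotypes)

    def test_in_block_error_count_binomial(self, bare_sketch):
        """At 1% genotyping error the in-block het count falls inside the
        binomial 99% interval."""
        blocks = simulate_autozygosity(bare_sketch, 0.5, 10_000_000, seed=3)
        genotypes = simulate_snp_genotypes(
            bare_sketch, blocks, genotyping_error_rate=0.01, seed=3
        )
        in_block = [
            g
            for g in genotypes
            if any(b.chrom == g.chrom and b.contains(g.pos) for b in blocks)
        ]
        n = len(in_block)
        assert n >= 5000
        hets = sum(g.zygosity == "het" for g in in_block)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= hets <= hi

    def test_spacing_larger_than_genome_rejected(self, bare_sketch):
        with pytest.raises(ValueError):
            simulate_snp_genotypes(
                bare_sketch, [], marker_spacing_bp=10**9, seed=0
            )

    def test_sorted_unique_positions(self, bare_sketch):
        genotypes = simulate_snp_genotypes(bare_sketch, [], seed=4)
        by_chrom = {}
        for g in genotypes:
            by_chrom.setdefault(g.chrom, []).append(g.pos)
        for positions in by_chrom.values():
            assert positions == sorted(positions)
            assert len(positions) == len(set(positions))


@pytest.fixture(scope="module")
def planted(small_sketch):
    blocks = simulate_autozygosity(small_sketch, 0.2, 4_000_000, seed=21)
    return plant_variants(
        small_sketch,
        blocks,
        counts_by_class={
            "coding_missense": 50, "coding_synonymous": 100, "noncoding": 500
        },
        db_membership_rates={
            "coding_missense": 0.9, "coding_synonymous": 0.9, "noncoding": 0.9
        },
        seed=21,
    )


class TestPlantVariants:
    def test_counts_conserved(self, planted):
        by_class = {}
        for v in planted.planted_variants:
            by_class[v.consequence] = by_class.get(v.consequence, 0) + 1
        assert by_class == {"missense": 50, "synonymous": 100, "noncoding": 500}
        assert len(planted.planted_variants) == 650

    def test_database_membership_binomial(self, planted):
        """~90% of non-causal variants are database members (99% interval)."""
        non_causal = [v for v in planted.planted_variants if not v.is_causal]
        members = sum(v.in_dbsnp for v in non_causal)
        lo, hi = binom.ppf([0.005, 0.995], len(non_causal), 0.9)
        assert lo <= members <= hi

    def test_causal_inside_exactly_one_block(self, planted):
        causal = planted.causal_variant
        assert causal is not None
        assert causal.zygosity == "hom"
        assert causal.consequence == "missense"
        assert not causal.in_dbsnp and not causal.in_kg
        hosts = [
            b
            for b in planted.aoh_blocks
            if b.chrom == causal.chrom and b.contains(causal.pos)
        ]
        assert len(hosts) == 1
        # strictly inside, with the configured flank margin
        assert causal.pos - hosts[0].start >= 51 * 10_000
        assert hosts[0].stop - causal.pos >= 51 * 10_000

    def test_unique_positions_per_chromosome(self, planted):
        keys = [(v.chrom, v.pos) for v in planted.planted_variants]
        assert len(keys) == len(set(keys))

    def test_causal_only_request(self, small_sketch):
        blocks = simulate_autozygosity(small_sketch, 0.2, 4_000_000, seed=22)
        truth = plant_variants(
            small_sketch, blocks,
            counts_by_class={
                "coding_missense": 1, "coding_synonymous": 0, "noncoding": 0
            },
            db_membership_rates={},
            seed=22,
        )
        assert len(truth.planted_variants) == 1
        assert truth.planted_variants[0].is_causal

    def test_no_host_block_is_error(self, small_sketch):
        with pytest.raises(ValueError):
            plant_variants(
                small_sketch, [],
                counts_by_class={
                    "coding_missense": 1, "coding_synonymous": 0, "noncoding": 0
                },
                db_membership_rates={},
                seed=0,
            )

    def test_planted_classes_verified_by_annotation(self, small_sketch):
        """Each planted coding variant annotates to its requested class."""
        from autozyg import annotate_consequence
        from autozyg.types import VariantCall

        blocks = simulate_autozygosity(small_sketch, 0.2, 4_000_000, seed=23)
        truth = plant_variants(
            small_sketch, blocks,
            counts_by_class={
                "coding_missense": 20, "coding_synonymous": 20,
                "coding_nonsense": 10, "noncoding": 20,
            },
            db_membership_rates={},
            seed=23,
        )
        for v in truth.planted_variants:
            call = VariantCall(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                zygosity=v.zygosity, depth_hq=50, alt_fraction=1.0,
                call_rate_percent=100,
            )
            ann = annotate_consequence(
                call, small_sketch.genes, small_sketch.reference
            )
            assert ann.consequence == v.consequence, v


class TestSimulatePileups:
    def test_homozygous_site_error_free(self, small_sketch):
        from autozyg.types import PlantedVariant, TruthSet

        gene = small_sketch.genes[10]
        pos = gene.cds_genomic_positions()[0]
        ref = small_sketch.reference.base(gene.chrom, pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        truth = TruthSet(
            aoh_blocks=(),
            planted_variants=(
                PlantedVariant(
                    chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                    zygosity="hom", consequence="missense",
                    gene_id=gene.gene_id, in_dbsnp=False, in_kg=False,
                ),
            ),
        )
        (column,) = simulate_pileups(
            truth, small_sketch, mean_depth=90, base_error_rate=0.0,
            quality_model={"p_low": 0.0}, seed=31, n_reference_positions=0,
        )
        assert column.counts_lo == {}
        assert set(column.counts_hi) == {alt}

    def test_empty_truth_and_no_targets_is_empty(self, small_sketch):
        from autozyg.types import TruthSet

        truth = TruthSet(aoh_blocks=(), planted_variants=())
        assert (
            simulate_pileups(truth, small_sketch, seed=0, n_reference_positions=0)
            == []
        )

    def test_determinism(self, small_sketch):
        from autozyg.types import TruthSet

        truth = TruthSet(aoh_blocks=(), planted_variants=())
        a = simulate_pileups(truth, small_sketch, seed=5, n_reference_positions=50)
        b = simulate_pileups(truth, small_sketch, seed=5, n_reference_positions=50)
        assert a == b


class TestToySketch:
    def test_gene_layout_invariants(self, small_sketch):
        sizes = dict(small_sketch.chromosomes)
        spans = {}
        for gene in small_sketch.genes:
            assert gene.start >= 1 and gene.stop - 1 <= sizes[gene.chrom]
            assert len(gene.cds_genomic_positions()) % 3 == 0
            spans.setdefault(gene.chrom, []).append((gene.start, gene.stop))
        for intervals in spans.values():
            intervals.sort()
            for a, b in zip(intervals, intervals[1:]):
                assert a[1] <= b[0]

    def test_sketch_determinism(self):
        a = make_toy_sketch(seed=3, n_genes=50)
        b = make_toy_sketch(seed=3, n_genes=50)
        assert a.genes == b.genes
        assert a.reference.seed == b.reference.seed
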