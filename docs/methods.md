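# Methods

## Scientific model

`autozyg` targets the classic homozygosity-mapping design for recessive
disease in a consanguineous proband. The offspring of first cousins is
expected to be autozygous over a fraction F = 1/16 of the genome, arranged
in long blocks inherited identical-by-descent through both parents. A
causal recessive allele lies inside such a block; therefore every SNP-array
marker flanking it is homozygous, and the exome's candidate set can be cut
to variants that are (i) coding, (ii) absent from catalogs of common
variation, (iii) homozygous, (iv) missense, and (v) located inside a
detected absence-of-heterozygosity (AOH) region.

The package treats this as five cooperating components: a synthetic-data
generator that emulates the study design with known truth, an AOH scanner,
a pileup genotype caller, a consequence annotator, and the filtering
cascade with reporting.

## AOH detection

Detection is a deterministic greedy rule over sorted genotypes, per
chromosome. From the leftmost homozygous marker not yet inside a reported
run, the run extends right while the heterozygous-marker count stays at or
below `max_het_in_run` and no gap between consecutive informative markers
exceeds `max_gap_bp`; trailing heterozygous markers are trimmed so runs
start and end on homozygous markers. A maximal extension is reported iff it
spans ≥ `min_length_bp` and ≥ `min_markers` informative markers. Missing
genotypes (array no-calls) are neutral: they never break a run, are not
counted, and do not enter gap computation — no-calls should not fragment
true runs. Reported runs never overlap, and an O(n²) per-start enumerator of
the same rule is kept in the test suite as an independent oracle.

Defaults: `min_markers = 50`, `min_length_bp = 3 Mb`, `max_gap_bp = 1 Mb`,
`max_het_in_run = 2`. The het tolerance is deliberately set above the
expected number of genotyping-error heterozygotes per multi-megabase block
(≈ 0.3–1 at the default error rate and marker density): with a tolerance of
1, two error heterozygotes landing in one block fragment it into pieces
that can fail `min_length_bp`, silently dropping the very interval that
hosts the causal variant. A tolerance of 2 absorbs that failure mode while
background heterozygosity (≈ 0.35 per marker outside blocks) still
terminates runs within a few markers, so chance runs never approach the
3 Mb threshold.

Coordinates follow one convention throughout: marker and variant positions
are 1-based; region intervals are half-open `[start, stop)` with
`length = stop − start`; BED output converts by `start − 1`. A gene or
variant exactly at `stop` does not overlap the region.

## Genotype calling

The caller consumes per-position base counts split at a base-quality
cutoff (default Q20, applied by the simulator when it splits counts).
Low-quality bases are excluded entirely. A position with fewer than
`min_depth = 10` high-quality bases is a no-call. Otherwise, with `f` the
fraction of high-quality bases carrying the most frequent non-reference
allele: `f > 0.75` → homozygous variant, `0.25 ≤ f ≤ 0.75` → heterozygous
variant (both boundaries inclusive, configurable), `f < 0.25` → no variant.
Ties between equally frequent non-reference bases break alphabetically for
determinism. The reported per-site "call rate" is the allele fraction as an
integer percent, rounded half away from zero — the reading under which 89
alternate reads versus 1 other read print as 99%. Indels and secondary
alternate alleles are out of scope.

VCF output is VCF 4.2 with `DPHQ` (high-quality depth), `AC` (high-quality
alternate count) and `AFRAC` INFO keys and a single-sample `GT` column; the
integer `AC` field lets a parsed record reconstruct the allele fraction
exactly, which the round-trip test (written here, parsed with cyvcf2)
relies on.

## Consequence annotation

A variant inside a gene's CDS is located in coding coordinates
(strand-aware; minus-strand alleles complemented), its codon rebuilt from
the reference accessor, the alternate base substituted, and both codons
translated with the standard nuclear code. `alt == ref` amino acid →
synonymous; alternate stop → nonsense; otherwise missense, reported as
`p.<Ref><Position><Alt>`. Everything outside a CDS is noncoding — the toy
gene models are fully coding, so UTR/intron subclassification is not
modelled. The test suite checks the per-codon path against a whole-CDS
retranslation oracle. The only pathogenicity-adjacent computation is a
conservation flag: true iff every non-gap residue in an alignment column
equals the reference residue.

## Filtering cascade

Steps run in a configurable order (default: total → coding → not in dbSNP →
not in 1000 Genomes → homozygous → missense → AOH chromosomes → within
AOH). Steps 2–5 are pure set filters, so the final candidate set is
invariant to their order (verified by permutation tests); only the
intermediate counts change. Nonsense variants are a distinct class and do
not pass the missense step. Database membership is an exact
(chrom, pos, ref, alt) match — the simplest defensible semantics. The
chromosome-restriction step is derived from the detected AOH regions at
run time, never hard-coded. Survivor counts are asserted non-increasing on
every run.

Flanking-homozygosity support counts consecutive homozygous markers
outward from a candidate until the first heterozygous marker on each side
(missing markers neutral). "Flanked by more than 50 homozygous SNPs" is
read per side (default `required = 51` on each flank), the stricter
interpretation consistent with "flanked"; a `total` mode sums both sides
instead.

## Synthetic proband generator

The generator is the package's study-design emulator, not a fixture: every
parameter is a config key and all randomness flows from one seed
(per-stage seeds are derived with `numpy` seed sequences; equal configs
give byte-identical artifact bundles).

* **Genome sketch** — 4 chromosomes × 50 Mb with 1,200 toy genes
  (2–4 fully coding exons of 120–240 bp), matching the human genome's
  ≈ 1 gene / 170 kb so that multi-megabase blocks always contain genes.
  The reference is a deterministic hash of (chromosome, position, seed):
  random-access, O(1) memory, byte-stable.
* **Autozygous blocks** — lengths exponential with mean 10 Mb truncated at
  `min_block_bp = 4 Mb` (the scale of blocks from a recent consanguineous
  loop), placed uniformly with overlap rejection until the total reaches
  F × genome length; the final block is trimmed/rounded so the realized
  total sits within half a minimum block of the target. Default F = 1/16.
* **Array genotypes** — a 10 kb grid with ±2.5 kb jitter (≈ 20,000
  markers). Outside blocks a marker is heterozygous with probability 0.35
  (a typical polymorphic-array het rate); inside, homozygous except
  genotyping errors reported het at 5×10⁻⁴ (high-end array reproducibility
  figures put the miscall rate at or below 10⁻³).
* **Planted variants** — per-class counts (defaults 150 missense /
  250 synonymous / 10 nonsense / 600 noncoding; the causal variant is one
  of the missense count). Coding changes are constructed codon-aware so the
  annotation layer reproduces the requested class; noncoding variants land
  outside genes. Mock dbSNP membership is Bernoulli per class (0.9 coding,
  0.95 noncoding — most common variation is catalogued); mock 1000 Genomes
  membership is drawn independently at 0.85 × the class rate, so the
  1000 Genomes step removes variants the dbSNP step missed, as a real
  two-catalog cascade does. The causal variant is homozygous missense,
  absent from both catalogs, and hosted by a gene lying at least
  `flank_n × marker spacing` (default 510 kb) inside a block, guaranteeing
  the flanking-marker bed.
* **Pileups** — depth Poisson with mean 56 (study-scale target coverage);
  each read carries the true allele (fair coin at heterozygous sites),
  suffers a uniform substitution error at rate 0.01, and is low-quality
  with probability 0.15, landing in the counts the caller ignores.
  Columns are emitted at every planted site plus 500 reference positions.

What the generator does **not** emulate: read-level artifacts (alignment
error, strand bias, indels, mapping ambiguity), LD structure and realistic
allele frequencies, CNVs, multi-sample pedigrees, or the genome-wide scale
of a real exome (70,812 variants; the published cascade totals are
mirrored structurally and by complement arithmetic, not numerically).
Passing recovery tests therefore demonstrates the correctness and
robustness of the decision rules under the stated noise models — not
calling performance on real sequencing data.

## Problem sizes and determinism

Default study conditions — 200 Mb genome, ≈ 20,000 markers, ≈ 1,000
planted variants, 56× depth — run end to end in well under a minute, and
the 20-replicate recovery experiment (seeds 1–20) recovers the planted
causal variant in 20/20 runs with a median final candidate list of 1.
Hypothesis-based property tests are derandomized; stochastic assertions use
fixed seeds and binomial/Poisson interval oracles, so the suite is fully
reproducible.

## Known limitations

* The AOH scan's greedy leftmost-maximal rule is one defensible choice
  among several; boundary placement can overshoot a true block edge by a
  few markers when the adjacent background happens to be homozygous.
* The caller has no genotype-likelihood model; near-threshold allele
  fractions at marginal depth are decided by hard cutoffs.
* The published chr4 AOH rows are internally inconsistent (printed length ≠
  stop − start); the fixture carries them as printed and pins the length
  convention only on the self-consistent rows.
* Database matching is exact-key; positional or allele-normalized matching
  (left-alignment, multi-allelic splitting) is out of scope along with
  indels.
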