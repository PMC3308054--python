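"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct method available —
linear scans, double loops, whole-protein retranslation, plain set algebra —
without sharing code paths with the package implementation it checks.
"""

from __future__ import annotations

from itertools import groupby

from Bio.Seq import Seq

from autozyg.types import complement


def scan_aoh_bruteforce(
    genotypes, min_markers, min_length_bp, max_het_in_run, max_gap_bp
):
    """O(n^2) per-start enumeration of the greedy leftmost-maximal runs."""
    regions = []
    for chrom, group in groupby(genotypes, key=lambda g: g.chrom):
        m = [g for g in group if g.zygosity != "missing"]
        n = len(m)
        i = 0
        while i < n:
            if m[i].zygosity != "hom":
                i += 1
                continue
            # Fresh maximal extension from i.
            j = i
            hets = 0
            for k in range(i + 1, n):
                if m[k].pos - m[k - 1].pos > max_gap_bp:
                    break
                h = hets + (m[k].zygosity == "het")
                if h > max_het_in_run:
                    break
                hets = h
                j = k
            while m[j].zygosity == "het":
                j -= 1
            if j - i + 1 >= min_markers and m[j].pos - m[i].pos >= min_length_bp:
                regions.append((chrom, m[i].pos, m[j].pos, j - i + 1))
                i = j + 1
            else:
                i += 1
    return regions


def intersect_bruteforce(variants, regions):
    """Plain double loop over variants x regions, half-open membership."""
    kept = []
    for v in variants:
        for r in regions:
            if r.chrom == v.chrom and r.start <= v.pos < r.stop:
                kept.append(v)
                break
    return kept


def flanking_bruteforce(variant, genotypes, required=51, mode="per_side"):
    """Linear scan outward from the variant over its chromosome's markers."""
    markers = [g for g in genotypes if g.chrom == variant.chrom]
    left = right = 0
    for g in reversed([g for g in markers if g.pos < variant.pos]):
        if g.zygosity == "missing":
            continue
        if g.zygosity == "het":
            break
        left += 1
    for g in [g for g in markers if g.pos > variant.pos]:
        if g.zygosity == "missing":
            continue
        if g.zygosity == "het":
            break
        right += 1
    if mode == "per_side":
        ok = left >= required and right >= required
    else:
        ok = left + right >= required
    return left, right, ok


def retranslate_oracle(gene, reference, pos, alt):
    """Consequence + protein change by full-CDS retranslation.

    Builds the entire coding sequence from the reference accessor, applies
    the substitution in CDS coordinates, translates both proteins, and
    classifies from the whole-protein diff.
    """
    positions = gene.cds_genomic_positions()
    if gene.strand == "+":
        cds = "".join(reference(gene.chrom, p) for p in positions)
        alt_base = alt
    else:
        cds = "".join(complement(reference(gene.chrom, p)) for p in positions)
        alt_base = complement(alt)
    i = positions.index(pos)
    mutated = cds[:i] + alt_base + cds[i + 1 :]
    prot_ref = str(Seq(cds).translate())
    prot_alt = str(Seq(mutated).translate())
    if prot_ref == prot_alt:
        return "synonymous", f"p.{prot_ref[i // 3]}{i // 3 + 1}{prot_alt[i // 3]}"
    diffs = [k for k, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    assert len(diffs) == 1
    k = diffs[0]
    aa_change = f"p.{prot_ref[k]}{k + 1}{prot_alt[k]}"
    if prot_alt[k] == "*":
        return "nonsense", aa_change
    return "missense", aa_change


def cascade_set_algebra(planted, blocks):
    """Final cascade survivors computed directly from truth flags."""
    return [
        v
        for v in planted
        if v.consequence == "missense"
        and v.zygosity == "hom"
        and not v.in_dbsnp
        and not v.in_kg
        and any(b.chrom == v.chrom and b.start <= v.pos < b.stop for b in blocks)
    ]
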