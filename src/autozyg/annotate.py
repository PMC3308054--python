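"""Coding-consequence annotation and the cross-species conservation flag.

Consequence calling locates a substitution inside a gene's CDS, rebuilds the
affected codon from the reference (reverse-complementing for minus-strand
genes), swaps in the alternate base, and translates both codons with the
standard nuclear genetic code.  Amino-acid changes are reported in the usual
short protein notation, e.g. ``p.G60V`` for glycine 60 to valine.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Iterable, Optional, Sequence, Union

from Bio.Seq import Seq

from autozyg.types import (
    AnnotatedVariant,
    GeneModel,
    VariantCall,
    complement,
)

ReferenceAccessor = Callable[[str, int], str]


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=4096)
def _cds_index(gene: GeneModel) -> tuple[tuple[int, ...], dict]:
    """(CDS positions in mRNA order, genomic position -> CDS index map)."""
    try:
        positions = tuple(gene.cds_genomic_positions())
    except ValueError as exc:
        raise ValueError(f"malformed CDS: {exc}") from exc
    return positions, {p: i for i, p in enumerate(positions)}


def _locate_in_cds(gene: GeneModel, pos: int) -> Optional[int]:
    """0-based index of a genomic position within the gene's coding sequence."""
    return _cds_index(gene)[1].get(pos)


def annotate_consequence(
    variant: VariantCall,
    genes: Iterable[GeneModel],
    reference: ReferenceAccessor,
    in_dbsnp: bool = False,
    in_kg: bool = False,
) -> AnnotatedVariant:
    """Assign a coding consequence and protein change to a variant call.

    A variant outside every CDS (intergenic, intronic, or UTR) is
    ``noncoding``.  Raises ``ValueError`` if the reference accessor disagrees
    with the call's reference allele, or if a containing gene has a malformed
    CDS.
    """
    ref_base = reference(variant.chrom, variant.pos)
    if ref_base != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"accessor says {ref_base}, call says {variant.ref}"
        )
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        if not (gene.start <= variant.pos < gene.stop):
            continue
        cds_index = _locate_in_cds(gene, variant.pos)
        if cds_index is None:
            continue
        codon_number = cds_index // 3
        offset = cds_index % 3
        codon_positions = _cds_index(gene)[0][
            codon_number * 3 : codon_number * 3 + 3
        ]
        ref_codon = "".join(
            reference(gene.chrom, p) if gene.strand == "+" else complement(reference(gene.chrom, p))
            for p in codon_positions
        )
        alt_base = variant.alt if gene.strand == "+" else complement(variant.alt)
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        if alt_aa == ref_aa:
            consequence = "synonymous"
        elif alt_aa == "*":
            consequence = "nonsense"
        else:
            consequence = "missense"
        return AnnotatedVariant(
            call=variant,
            consequence=consequence,
            gene_id=gene.gene_id,
            aa_change=f"p.{ref_aa}{codon_number + 1}{alt_aa}",
            in_dbsnp=in_dbsnp,
            in_kg=in_kg,
        )
    return AnnotatedVariant(
        call=variant,
        consequence="noncoding",
        gene_id=None,
        aa_change=None,
        in_dbsnp=in_dbsnp,
        in_kg=in_kg,
    )


def conservation_flag(
    alignment: Union[Sequence[str], Sequence[tuple[str, str]], object],
    column_index: int,
    reference_residue: str,
) -> bool:
    """True iff every non-gap residue in an alignment column equals the reference.

    Accepts a Biopython ``MultipleSeqAlignment``, a list of aligned sequence
    strings, a list of ``(name, sequence)`` pairs, or a list of SeqRecords.
    Gap characters (``-`` and ``.``) are ignored; an all-gap column is an
    error.
    """
    rows: list[str] = []
    for entry in alignment:
        if isinstance(entry, str):
            rows.append(entry)
        elif isinstance(entry, tuple):
            rows.append(str(entry[1]))
        else:  # SeqRecord or alignment row
            rows.append(str(entry.seq))
    if not rows:
        raise ValueError("empty alignment")
    for row in rows:
        if not (0 <= column_index < len(row)):
            raise ValueError(
                f"column {column_index} outside alignment of width {len(row)}"
            )
    residues = [row[column_index] for row in rows if row[column_index] not in "-."]
    if not residues:
        raise ValueError(f"alignment column {column_index} is all gaps")
    return all(r == reference_residue for r in residues)
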