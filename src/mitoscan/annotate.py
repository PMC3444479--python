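"""Gene-level annotation of mtDNA variants.

Positions are looked up in a gene coordinate table (closed 1-based
intervals). For SNVs inside protein-coding genes the codon index is computed
with codon 1 = the first three coding bases from the gene start, and the
synonymous flag by translating the reference vs. alternate codon under the
vertebrate mitochondrial genetic code.

Note on codon numbering: the codon index is pure arithmetic from the
annotated gene start. Some published labels for ND1 variants use a different
numbering convention; this package always reports the arithmetic index.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .reference import ReferenceSequence
from .variants import SNV, Variant

_VMITO = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    start: int
    end: int
    strand: str
    coding: bool

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be + or -")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def load_gene_table(path: Union[str, Path, None] = None) -> list[GeneAnnotation]:
    """Load gene coordinates (TSV: gene, start, end, strand, coding).

    With no path, the bundled human mtDNA table (standard MITOMAP/rCRS
    coordinates) is used.
    """
    if path is None:
        source = resources.files("mitoscan.data").joinpath("mito_genes.tsv")
        with source.open("r") as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(r.gene, int(r.start), int(r.end), r.strand, bool(int(r.coding)))
        for r in df.itertuples(index=False)
    ]


def translate_codon(codon: str) -> str:
    """One-letter amino acid under the vertebrate mitochondrial code ('*' = stop)."""
    codon = codon.upper()
    if codon in _VMITO.stop_codons:
        return "*"
    return _VMITO.forward_table[codon]


def annotate_variant(
    v: Variant,
    genes: list[GeneAnnotation],
    reference: ReferenceSequence,
) -> tuple[Optional[str], Optional[int], Optional[bool]]:
    """Return (gene, codon index, synonymous flag) for a variant.

    Non-genic positions return (None, None, None); non-coding genes (rRNA,
    tRNA) and indels return codon/synonymous as None. For positions in
    overlapping genes the coding gene with the smallest start wins.
    """
    hits = [g for g in genes if g.contains(v.position)]
    if not hits:
        return None, None, None
    coding_hits = sorted((g for g in hits if g.coding), key=lambda g: g.start)
    if not coding_hits or v.kind != SNV:
        g = coding_hits[0] if coding_hits else sorted(hits, key=lambda g: g.start)[0]
        return g.gene, None, None
    g = coding_hits[0]
    if g.strand == "+":
        offset = v.position - g.start
        codon_index = offset // 3 + 1
        codon_start = g.start + 3 * (codon_index - 1)
        if codon_start + 2 > g.end:
            return g.gene, codon_index, None  # truncated terminal codon
        ref_codon = reference.slice(codon_start, codon_start + 2)
        within = v.position - codon_start
        alt_codon = ref_codon[:within] + v.alt_allele + ref_codon[within + 1 :]
    else:
        offset = g.end - v.position
        codon_index = offset // 3 + 1
        codon_end = g.end - 3 * (codon_index - 1)
        if codon_end - 2 < g.start:
            return g.gene, codon_index, None
        fwd = reference.slice(codon_end - 2, codon_end)
        within = v.position - (codon_end - 2)
        alt_fwd = fwd[:within] + v.alt_allele + fwd[within + 1 :]
        ref_codon = str(Seq(fwd).reverse_complement())
        alt_codon = str(Seq(alt_fwd).reverse_complement())
    synonymous = translate_codon(ref_codon) == translate_codon(alt_codon)
    return g.gene, codon_index, synonymous
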