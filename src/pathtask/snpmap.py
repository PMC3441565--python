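"""Collapse SNP-level genotypes to gene level via phenotype association.

Each gene is represented by the single SNP in its window with the strongest
Pearson chi-square association with phenotype, subject to a minor-allele
frequency filter.  The window runs from ``upstream`` bases upstream of the
transcription start site to the end of the transcribed region, so its shape
depends on strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .types import (
    GeneAnnotation,
    GenotypeMatrix,
    PhenotypeLabels,
    SnpLocation,
)

__all__ = [
    "GeneSnpAssignment",
    "snps_in_gene_window",
    "chi_square_association",
    "minor_allele_frequency",
    "select_representative_snps",
    "collapse_to_gene_level",
]


@dataclass
class GeneSnpAssignment:
    """gene_id -> (snp_id, chi-square value, minor allele frequency)."""

    mapping: dict

    def __post_init__(self):
        for gene, (snp, chi2, maf) in self.mapping.items():
            if chi2 < 0:
                raise ValueError(f"{gene}: negative chi-square value")
            if not (0 <= maf <= 0.5):
                raise ValueError(f"{gene}: MAF {maf} outside [0, 0.5]")

    def __len__(self) -> int:
        return len(self.mapping)

    def snp_for(self, gene_id: str) -> str:
        return self.mapping[gene_id][0]


def snps_in_gene_window(
    gene: GeneAnnotation, snps: Sequence[SnpLocation], upstream: int = 1000
) -> list:
    """SNP ids on the gene's chromosome within its strand-aware window.

    For + strand genes the window is [max(1, tx_start - upstream), tx_end];
    for - strand genes it is [tx_start, tx_end + upstream] (the TSS sits at
    tx_end, so "upstream" extends past it).
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    if gene.strand == "+":
        lo, hi = max(1, gene.tx_start - upstream), gene.tx_end
    else:
        lo, hi = gene.tx_start, gene.tx_end + upstream
    return [
        s.snp_id
        for s in snps
        if s.chromosome == gene.chromosome and lo <= s.position <= hi
    ]


def chi_square_association(calls: np.ndarray, labels: PhenotypeLabels) -> float:
    """Pearson chi-square of the 2 x k class-by-genotype contingency table.

    k is the number of genotype categories observed in the pooled cohort;
    no continuity correction.  A single observed category is degenerate and
    scores 0.
    """
    calls = np.asarray(calls)
    if calls.shape != (labels.n_samples,):
        raise ValueError("calls length does not match sample count")
    categories = np.unique(calls)
    if len(categories) < 2:
        return 0.0
    table = np.array(
        [
            [(calls[labels.y == k] == c).sum() for c in categories]
            for k in (0, 1)
        ]
    )
    stat, _, _, _ = sstats.chi2_contingency(table, correction=False)
    return float(stat)


def minor_allele_frequency(calls: np.ndarray) -> float:
    """min(f, 1-f) where f is the frequency of the counted allele."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("no genotype calls")
    f = calls.sum() / (2 * calls.size)
    return float(min(f, 1.0 - f))


def select_representative_snps(
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpLocation],
    genotypes: GenotypeMatrix,
    labels: PhenotypeLabels,
    upstream: int = 1000,
    maf_min: float = 0.05,
) -> GeneSnpAssignment:
    """Pick, per gene, the window SNP with maximal chi-square association.

    Only SNPs with MAF > ``maf_min`` are eligible; genes with no eligible
    SNP are omitted.  Chi-square ties break to the smallest genomic
    position, then lexicographic snp_id.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    if list(genotypes.sample_ids) != list(labels.sample_ids):
        raise ValueError("genotype and label sample ids are not aligned")
    row_of = {s: i for i, s in enumerate(genotypes.snp_ids)}
    pos_of = {s.snp_id: s.position for s in snps}
    mapping: dict = {}
    for gene in genes:
        best = None
        for snp_id in snps_in_gene_window(gene, snps, upstream):
            if snp_id not in row_of:
                continue
            calls = genotypes.calls[row_of[snp_id]]
            maf = minor_allele_frequency(calls)
            if maf <= maf_min:
                continue
            chi2 = chi_square_association(calls, labels)
            key = (-chi2, pos_of[snp_id], snp_id)
            if best is None or key < best[0]:
                best = (key, snp_id, chi2, maf)
        if best is not None:
            mapping[gene.gene_id] = (best[1], best[2], best[3])
    return GeneSnpAssignment(mapping)


def collapse_to_gene_level(
    genotypes: GenotypeMatrix, assignment: GeneSnpAssignment
) -> GenotypeMatrix:
    """Re-key the genotype matrix by gene, copying each gene's representative SNP row."""
    row_of = {s: i for i, s in enumerate(genotypes.snp_ids)}
    gene_ids, rows = [], []
    for gene, (snp_id, _, _) in assignment.mapping.items():
        if snp_id not in row_of:
            raise ValueError(f"assigned SNP {snp_id!r} (gene {gene!r}) not in matrix")
        gene_ids.append(gene)
        rows.append(genotypes.calls[row_of[snp_id]])
    return GenotypeMatrix(gene_ids, list(genotypes.sample_ids), np.array(rows))
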