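"""Readers and writers for the standard formats the framework touches.

Supported formats: GCT v1.2 expression matrices, two-class CLS phenotype
files (categorical and numeric 0/1 dialects), GMT gene-set collections,
PLINK PED+MAP genotype files, plain TSV dosage matrices, and a BED-like
gene-annotation table.  Coordinates are 1-based inclusive everywhere;
0-based BED starts are shifted at parse time.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
    SnpLocation,
)

__all__ = [
    "read_expression_gct",
    "write_expression_gct",
    "read_labels_cls",
    "write_labels_cls",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "filter_gene_sets",
    "read_genotypes",
    "read_genotypes_ped",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_gene_annotations",
    "read_snp_locations_map",
]


# ---------------------------------------------------------------------------
# GCT

def read_expression_gct(path) -> ExpressionMatrix:
    """Read a GCT v1.2 expression matrix (genes in file order)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: dimension line must have 2 fields")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0].upper() != "NAME":
            raise ValueError(f"{path}: third line must start with NAME\\tDescription")
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise ValueError(
                f"{path}: header lists {len(sample_ids)} samples, "
                f"dimension line declares {n_samples}"
            )
        gene_ids, descriptions, rows = [], [], []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_samples + 2:
                raise ValueError(
                    f"{path}: row {fields[0]!r} has {len(fields) - 2} values, "
                    f"expected {n_samples}"
                )
            gene_ids.append(fields[0])
            descriptions.append(fields[1])
            rows.append([float(v) for v in fields[2:]])
    if len(gene_ids) != n_genes:
        raise ValueError(
            f"{path}: declares {n_genes} genes but contains {len(gene_ids)} rows"
        )
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows), descriptions)


def write_expression_gct(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    desc = expr.descriptions or ["na"] * expr.n_genes
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for g, d, row in zip(expr.gene_ids, desc, expr.values):
            fh.write(g + "\t" + d + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# CLS

def read_labels_cls(path, sample_ids: Sequence[str] | None = None) -> PhenotypeLabels:
    """Read a two-class CLS file.

    Accepts both the categorical dialect (labels repeat the class names from
    the '#' line) and the numeric dialect (0/1 indices into that line).  The
    first named class becomes C1.  ``sample_ids`` may supply real sample
    names; otherwise s1..sN are generated.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS needs 3 non-empty lines")
    counts = lines[0].split()
    n, n_classes = int(counts[0]), int(counts[1])
    if n_classes != 2:
        raise ValueError(f"{path}: only two-class CLS supported, got {n_classes}")
    if not lines[1].startswith("#"):
        raise ValueError(f"{path}: second line must start with '#'")
    names = lines[1][1:].split()
    if len(names) != 2:
        raise ValueError(f"{path}: expected 2 class names, got {len(names)}")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise ValueError(
            f"{path}: count line declares {n} samples, label line has {len(tokens)}"
        )
    if set(tokens) <= set(names):
        y = np.array([0 if t == names[0] else 1 for t in tokens])
    elif all(t.lstrip("-").isdigit() for t in tokens):
        idx = np.array([int(t) for t in tokens])
        if not np.isin(idx, (0, 1)).all():
            raise ValueError(f"{path}: numeric labels must be 0 or 1")
        y = idx
    else:
        bad = sorted(set(tokens) - set(names))
        raise ValueError(f"{path}: unknown class labels {bad}")
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    elif len(sample_ids) != n:
        raise ValueError(f"{path}: {len(sample_ids)} sample ids for {n} labels")
    return PhenotypeLabels(list(sample_ids), y, (names[0], names[1]))


def write_labels_cls(labels: PhenotypeLabels, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{labels.n_samples} 2 1\n")
        fh.write("# " + " ".join(labels.class_names) + "\n")
        fh.write(" ".join(labels.names_per_sample()) + "\n")


# ---------------------------------------------------------------------------
# GMT

def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a GMT file; duplicate member genes within a line are collapsed."""
    path = Path(path)
    sets: dict = {}
    descriptions: dict = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} fields)"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 15,
    max_size: int = 100,
) -> GeneSetCollection:
    """Restrict sets to a gene universe and keep those with min..max mapped genes.

    Bounds are inclusive; membership is replaced by the intersection with the
    universe (original member order preserved).
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("need 1 <= min_size <= max_size")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    kept: dict = {}
    descriptions: dict = {}
    for name, members in collection.sets.items():
        mapped = [g for g in members if g in universe_set]
        if min_size <= len(mapped) <= max_size:
            kept[name] = mapped
            if name in collection.descriptions:
                descriptions[name] = collection.descriptions[name]
    return GeneSetCollection(kept, descriptions)


# ---------------------------------------------------------------------------
# Genotypes

def read_genotypes(ped=None, map_=None, tsv=None):
    """Read genotype calls from a PED/MAP pair or a TSV dosage matrix.

    Returns ``(GenotypeMatrix, locations)`` where ``locations`` is a list of
    :class:`SnpLocation` for PED/MAP input and ``None`` for TSV input.
    """
    if tsv is not None:
        if ped is not None or map_ is not None:
            raise ValueError("pass either ped+map_ or tsv, not both")
        return read_genotypes_tsv(tsv), None
    if ped is None or map_ is None:
        raise ValueError("PED input needs both ped and map_ paths")
    return read_genotypes_ped(ped, map_)


def read_snp_locations_map(path) -> list:
    """Read a PLINK MAP file (chrom, snp_id, [cM,] bp position)."""
    path = Path(path)
    locations = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) == 4:
            chrom, snp_id, _, pos = fields
        elif len(fields) == 3:
            chrom, snp_id, pos = fields
        else:
            raise ValueError(f"{path}:{lineno}: MAP line needs 3 or 4 fields")
        locations.append(SnpLocation(snp_id, chrom, int(pos)))
    return locations


def read_genotypes_ped(ped_path, map_path):
    """Read a biallelic PED/MAP pair into minor-allele dosages.

    The minor allele is determined empirically over the whole file; frequency
    ties break to the lexicographically smaller allele.  Missing calls
    (allele code '0') are rejected.
    """
    locations = read_snp_locations_map(map_path)
    n_snps = len(locations)
    ped_path = Path(ped_path)
    sample_ids = []
    allele_rows = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_snps:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields for "
                f"{n_snps} SNPs, got {len(fields)}"
            )
        sample_ids.append(fields[1])
        allele_rows.append(fields[6:])
    alleles = np.array(allele_rows)  # samples x (2*n_snps)
    n_samples = len(sample_ids)
    calls = np.zeros((n_snps, n_samples), dtype=int)
    for j, loc in enumerate(locations):
        a = alleles[:, 2 * j]
        b = alleles[:, 2 * j + 1]
        if (a == "0").any() or (b == "0").any():
            raise ValueError(f"{ped_path}: missing genotype call at SNP {loc.snp_id}")
        observed, counts = np.unique(np.concatenate([a, b]), return_counts=True)
        if len(observed) > 2:
            raise ValueError(
                f"{ped_path}: SNP {loc.snp_id} is not biallelic "
                f"(alleles {sorted(observed)})"
            )
        if len(observed) == 1:
            continue  # monomorphic: minor allele absent, dosage stays 0
        order = np.lexsort((observed, counts))  # rarest first, ties lexicographic
        minor = observed[order[0]]
        calls[j] = (a == minor).astype(int) + (b == minor).astype(int)
    return GenotypeMatrix([l.snp_id for l in locations], sample_ids, calls), locations


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a TSV dosage matrix: SNPs as rows, samples as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = df.to_numpy()
    return GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], calls
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.calls, index=geno.snp_ids, columns=geno.sample_ids)
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene annotations

def read_gene_annotations(path, zero_based_starts: bool = False) -> list:
    """Read a gene-annotation TSV: gene_id, chrom, strand, tx_start, tx_end.

    A header line is detected and skipped.  With ``zero_based_starts`` the
    start column is interpreted as 0-based half-open (BED style) and shifted
    to 1-based inclusive.
    """
    path = Path(path)
    genes = []
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, 1):
            if not fields or not "".join(fields).strip():
                continue
            if lineno == 1 and not fields[3].lstrip("-").isdigit():
                continue  # header
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: need 5 columns")
            gene_id, chrom, strand, start, end = fields[:5]
            start = int(start) + (1 if zero_based_starts else 0)
            genes.append(GeneAnnotation(gene_id, chrom, strand, start, int(end)))
    return genes
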