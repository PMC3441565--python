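"""Core containers for expression, genotype, phenotype and gene-set data.

All matrices are dense numpy arrays with explicit, ordered row/column
identifiers.  Phenotypes are strictly two-class; the first class (``C1``)
is the "positive" class throughout: correlation statistics are oriented
towards it and SVM decision values above zero predict it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "PhenotypeLabels",
    "GeneSetCollection",
    "GeneAnnotation",
    "SnpLocation",
    "SampleStatMatrix",
    "EnrichmentMatrix",
    "ensure_same_samples",
]


def _find_duplicate(ids: Sequence[str]):
    seen = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def _check_unique(ids: Sequence[str], kind: str) -> list:
    ids = list(ids)
    dup = _find_duplicate(ids)
    if dup is not None:
        raise ValueError(f"duplicate {kind} id: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of continuous expression values."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    descriptions: list | None = None

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.descriptions is not None and len(self.descriptions) != len(self.gene_ids):
            raise ValueError("descriptions length does not match gene count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reorder_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = _reorder_index(self.sample_ids, sample_ids)
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx],
            None if self.descriptions is None else list(self.descriptions),
        )


@dataclass
class GenotypeMatrix:
    """SNPs (or genes, after collapsing) x samples allele-dosage matrix.

    Entries count copies of the designated allele and must lie in {0, 1, 2}.
    """

    snp_ids: list
    sample_ids: list
    calls: np.ndarray

    def __post_init__(self):
        self.snp_ids = _check_unique(self.snp_ids, "snp")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snp_ids)} snps x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.calls.dtype, np.integer):
            as_int = self.calls.astype(int)
            if not np.array_equal(as_int, self.calls):
                raise ValueError("genotype calls must be integers")
            self.calls = as_int
        if self.calls.size and not np.isin(self.calls, (0, 1, 2)).all():
            bad = self.calls[~np.isin(self.calls, (0, 1, 2))].flat[0]
            raise ValueError(f"genotype call {bad!r} outside {{0,1,2}}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reorder_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = _reorder_index(self.sample_ids, sample_ids)
        return GenotypeMatrix(list(self.snp_ids), list(sample_ids), self.calls[:, idx])


@dataclass
class PhenotypeLabels:
    """Two-class phenotype assignment.

    ``y`` holds 0 for the first class (C1) and 1 for the second (C2).
    Class-conditional statistics require at least two samples per class.
    """

    sample_ids: list
    y: np.ndarray
    class_names: tuple = ("C1", "C2")

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.y = np.asarray(self.y, dtype=int)
        if self.y.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match sample count")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 (C1) or 1 (C2)")
        if len(self.class_names) != 2 or self.class_names[0] == self.class_names[1]:
            raise ValueError("need two distinct class names")
        n1 = int((self.y == 0).sum())
        n2 = int((self.y == 1).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"need at least 2 samples per class (got {n1} {self.class_names[0]}, "
                f"{n2} {self.class_names[1]})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def signed(self) -> np.ndarray:
        """Encode C1 as +1 and C2 as -1."""
        return np.where(self.y == 0, 1.0, -1.0)

    def names_per_sample(self) -> list:
        return [self.class_names[v] for v in self.y]

    def reorder_samples(self, sample_ids: Sequence[str]) -> "PhenotypeLabels":
        idx = _reorder_index(self.sample_ids, sample_ids)
        return PhenotypeLabels(list(sample_ids), self.y[idx], self.class_names)


@dataclass
class GeneSetCollection:
    """Named gene sets; member lists are duplicate-free and ordered."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            members = list(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            dup = _find_duplicate(members)
            if dup is not None:
                raise ValueError(f"gene set {name!r} lists gene {dup!r} twice")
            self.sets[name] = members

    @property
    def set_names(self) -> list:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]


@dataclass
class GeneAnnotation:
    """Transcript span of a gene, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.tx_start <= self.tx_end):
            raise ValueError(
                f"{self.gene_id}: need 1 <= tx_start <= tx_end, got "
                f"[{self.tx_start}, {self.tx_end}]"
            )


@dataclass
class SnpLocation:
    snp_id: str
    chromosome: str
    position: int

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


@dataclass
class SampleStatMatrix:
    """Per-sample, per-gene correlation statistics s_ij (samples x genes)."""

    sample_ids: list
    gene_ids: list
    stats: np.ndarray

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"stats shape {self.stats.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("non-finite correlation statistics")


@dataclass
class EnrichmentMatrix:
    """Samples x gene-sets enrichment scores.

    Raw (un-normalized) scores are signed KS statistics and lie in [-1, 1];
    permutation-normalized scores may exceed that range.
    """

    sample_ids: list
    set_names: list
    scores: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.set_names = _check_unique(self.set_names, "gene set")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.set_names)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.set_names)} sets"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite enrichment scores")
        if not self.normalized and self.scores.size:
            if np.abs(self.scores).max() > 1.0 + 1e-9:
                raise ValueError("raw enrichment scores must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _reorder_index(current: Sequence[str], wanted: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(current)}
    missing = [s for s in wanted if s not in pos]
    if missing or len(wanted) != len(current):
        raise ValueError(
            f"cannot reorder: sample sets differ (first missing: {missing[:3]})"
        )
    return np.array([pos[s] for s in wanted], dtype=int)


def ensure_same_samples(*objs) -> None:
    """Raise unless all objects carry an identical ordered sample-id list.

    Misalignment is an error, never a silent intersection.
    """
    if not objs:
        return
    ref = list(objs[0].sample_ids)
    for o in objs[1:]:
        if list(o.sample_ids) != ref:
            raise ValueError(
                "sample ids are not aligned across inputs; reorder explicitly "
                "with .reorder_samples()"
            )
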