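"""Sample-specific gene-set enrichment scores.

The pipeline has two stages.  First, a per-sample, per-gene *correlation
statistic* s_ij measures how much sample i's value at gene j resembles the
class-C1 profile of that gene versus the class-C2 profile:

* expression: the log-likelihood ratio of class-conditional Gaussian
  densities, log f_C1,j(x_ij) - log f_C2,j(x_ij);
* genotype: log(p1 / p2), where p_k is the fraction of class-k samples
  carrying sample i's genotype at gene j (with a pseudo-count of 1 added to
  both counts and both denominators whenever either count is zero).

Second, for each sample the genes are ranked by decreasing s_ij and a
weighted Kolmogorov-Smirnov running sum converts each gene set into a signed
enrichment score in [-1, 1]: member genes add |s|^p normalized by the member
total, non-members subtract 1/(G - m), and the score is the running-sum value
of maximal absolute deviation from zero.

Scores can optionally be normalized against label-permutation backgrounds.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np

from .types import (
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
    SampleStatMatrix,
)

__all__ = [
    "GaussianProfiles",
    "KernelDensityProfiles",
    "GenotypeProfiles",
    "expression_correlation_stats",
    "genotype_correlation_stats",
    "sample_enrichment_score",
    "enrichment_matrix",
    "normalize_enrichment",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation statistics: expression

class GaussianProfiles:
    """Class-conditional Gaussian profiles per gene, for expression data.

    Fitted on a training cohort; scores any cohort measured on the same
    genes.  Training samples can be scored with leave-self-out estimates of
    their own class's mean and standard deviation, which avoids
    self-inflation with small cohorts.

    Standard deviations use the population convention (ddof=0) and are
    floored at ``max(sd, floor_frac * |mean|, floor_abs)`` so constant genes
    never produce infinite statistics.
    """

    def __init__(self, floor_frac: float = 0.2, floor_abs: float = 1e-8):
        self.floor_frac = floor_frac
        self.floor_abs = floor_abs

    def fit(self, expr: ExpressionMatrix, labels: PhenotypeLabels) -> "GaussianProfiles":
        if list(expr.sample_ids) != list(labels.sample_ids):
            raise ValueError("expression and label sample ids are not aligned")
        self.gene_ids_ = list(expr.gene_ids)
        self._X = expr.values.T.copy()  # samples x genes
        self._y = labels.y.copy()
        self._sample_ids = list(expr.sample_ids)
        self.mean_ = np.empty((2, expr.n_genes))
        self.sd_ = np.empty((2, expr.n_genes))
        for k in (0, 1):
            Xk = self._X[self._y == k]
            self.mean_[k] = Xk.mean(axis=0)
            self.sd_[k] = self._floor(Xk.std(axis=0, ddof=0), self.mean_[k])
        return self

    def _floor(self, sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
        return np.maximum(sd, np.maximum(self.floor_frac * np.abs(mean), self.floor_abs))

    @staticmethod
    def _log_density(x, mean, sd):
        return -np.log(sd) - 0.5 * ((x - mean) / sd) ** 2

    def score(self, expr: ExpressionMatrix) -> SampleStatMatrix:
        """Score a cohort against the fitted class profiles (no leave-self-out)."""
        if list(expr.gene_ids) != self.gene_ids_:
            raise ValueError("gene ids do not match the fitted profiles")
        X = expr.values.T
        stats = self._log_density(X, self.mean_[0], self.sd_[0]) - self._log_density(
            X, self.mean_[1], self.sd_[1]
        )
        return SampleStatMatrix(list(expr.sample_ids), list(self.gene_ids_), stats)

    def score_training(self, leave_self_out: bool = True) -> SampleStatMatrix:
        """Score the training cohort itself.

        With ``leave_self_out`` each sample's own class profile is
        re-estimated without that sample.
        """
        X, y = self._X, self._y
        stats = np.empty_like(X)
        for k in (0, 1):
            other = 1 - k
            rows = np.where(y == k)[0]
            Xk = X[rows]
            if leave_self_out:
                n = len(rows)
                s1 = Xk.sum(axis=0)
                s2 = (Xk**2).sum(axis=0)
                loo_mean = (s1 - Xk) / (n - 1)
                loo_var = (s2 - Xk**2) / (n - 1) - loo_mean**2
                loo_sd = self._floor(np.sqrt(np.maximum(loo_var, 0.0)), loo_mean)
                own = self._log_density(Xk, loo_mean, loo_sd)
            else:
                own = self._log_density(Xk, self.mean_[k], self.sd_[k])
            cross = self._log_density(Xk, self.mean_[other], self.sd_[other])
            stats[rows] = (own - cross) if k == 0 else (cross - own)
        return SampleStatMatrix(list(self._sample_ids), list(self.gene_ids_), stats)


class KernelDensityProfiles:
    """Class-conditional Gaussian-kernel densities per gene (KDE variant).

    Nonparametric alternative to :class:`GaussianProfiles`: each class's
    density for a gene is a Gaussian kernel mixture over that class's
    observed values, with a per-gene Silverman bandwidth
    ``h = factor * sd * n^(-1/5)`` (floored to stay positive).  Scoring is
    O(n_score * n_train) per gene, so this is meant for moderate cohorts.
    """

    def __init__(self, bandwidth_factor: float = 1.0, min_bandwidth: float = 1e-3):
        self.bandwidth_factor = bandwidth_factor
        self.min_bandwidth = min_bandwidth

    def fit(
        self, expr: ExpressionMatrix, labels: PhenotypeLabels
    ) -> "KernelDensityProfiles":
        if list(expr.sample_ids) != list(labels.sample_ids):
            raise ValueError("expression and label sample ids are not aligned")
        self.gene_ids_ = list(expr.gene_ids)
        self._X = expr.values.T.copy()
        self._y = labels.y.copy()
        self._sample_ids = list(expr.sample_ids)
        self.h_ = np.empty((2, expr.n_genes))
        for k in (0, 1):
            Xk = self._X[self._y == k]
            silverman = Xk.std(axis=0, ddof=0) * len(Xk) ** (-0.2)
            self.h_[k] = np.maximum(
                self.bandwidth_factor * silverman, self.min_bandwidth
            )
        return self

    def _log_density(self, X: np.ndarray, k: int, self_rows=None) -> np.ndarray:
        """log KDE of class k at X (n x G); ``self_rows`` maps each scored
        row to its own index within class k's data, to be excluded."""
        from scipy.special import logsumexp

        Xk = self._X[self._y == k]  # (nk, G)
        h = self.h_[k]
        # (n, nk, G) kernel log-contributions, genes chunked to bound memory
        n, G = X.shape
        nk = len(Xk)
        out = np.empty((n, G))
        chunk = max(1, int(2e6 / (n * nk)))
        for lo in range(0, G, chunk):
            hi = min(lo + chunk, G)
            z = (X[:, None, lo:hi] - Xk[None, :, lo:hi]) / h[lo:hi]
            logk = -0.5 * z**2
            if self_rows is not None:
                logk[np.arange(n), self_rows] = -np.inf
            out[:, lo:hi] = logsumexp(logk, axis=1)
        n_eff = nk if self_rows is None else nk - 1
        return out - np.log(n_eff * h * np.sqrt(2 * np.pi))

    def score(self, expr: ExpressionMatrix) -> SampleStatMatrix:
        if list(expr.gene_ids) != self.gene_ids_:
            raise ValueError("gene ids do not match the fitted profiles")
        X = expr.values.T
        stats = self._log_density(X, 0) - self._log_density(X, 1)
        return SampleStatMatrix(list(expr.sample_ids), list(self.gene_ids_), stats)

    def score_training(self, leave_self_out: bool = True) -> SampleStatMatrix:
        X, y = self._X, self._y
        stats = np.empty_like(X)
        for k in (0, 1):
            rows = np.where(y == k)[0]
            own_idx = np.arange(len(rows)) if leave_self_out else None
            own = self._log_density(X[rows], k, self_rows=own_idx)
            cross = self._log_density(X[rows], 1 - k)
            stats[rows] = (own - cross) if k == 0 else (cross - own)
        return SampleStatMatrix(list(self._sample_ids), list(self.gene_ids_), stats)


def expression_correlation_stats(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    leave_self_out: bool = True,
    floor_frac: float = 0.2,
    method: str = "gaussian",
) -> SampleStatMatrix:
    """Expression statistics for a cohort against itself.

    ``method`` selects the class-conditional density estimate: ``gaussian``
    (parametric log-likelihood ratio, the default) or ``kde`` (Gaussian
    kernel mixture).
    """
    if method == "gaussian":
        prof = GaussianProfiles(floor_frac=floor_frac).fit(expr, labels)
    elif method == "kde":
        prof = KernelDensityProfiles().fit(expr, labels)
    else:
        raise ValueError("method must be 'gaussian' or 'kde'")
    return prof.score_training(leave_self_out=leave_self_out)


# ---------------------------------------------------------------------------
# Correlation statistics: genotype

class GenotypeProfiles:
    """Class-conditional genotype frequencies per gene, for dosage data."""

    def fit(self, geno: GenotypeMatrix, labels: PhenotypeLabels) -> "GenotypeProfiles":
        if list(geno.sample_ids) != list(labels.sample_ids):
            raise ValueError("genotype and label sample ids are not aligned")
        self.gene_ids_ = list(geno.snp_ids)
        calls = geno.calls  # genes x samples
        y = labels.y
        self.n_ = np.array([(y == 0).sum(), (y == 1).sum()])
        # counts[k, gene, genotype value]
        self.counts_ = np.stack(
            [
                np.stack([(calls[:, y == k] == v).sum(axis=1) for v in (0, 1, 2)], axis=1)
                for k in (0, 1)
            ]
        )
        self._sample_ids = list(geno.sample_ids)
        self._calls = calls.copy()
        self._y = y.copy()
        return self

    def score(self, geno: GenotypeMatrix) -> SampleStatMatrix:
        if list(geno.snp_ids) != self.gene_ids_:
            raise ValueError("gene ids do not match the fitted profiles")
        return self._score_calls(geno.calls, list(geno.sample_ids))

    def score_training(self, leave_self_out: bool = True) -> SampleStatMatrix:
        """Score the training cohort itself.

        With ``leave_self_out`` each sample is removed from its own class's
        genotype counts before forming the frequency ratio.  Without it a
        sample always finds itself, which biases every gene's statistic
        towards the sample's own class and makes even noise gene sets look
        class-informative in training.
        """
        return self._score_calls(
            self._calls, self._sample_ids,
            self._y if leave_self_out else None,
        )

    def _score_calls(
        self, calls: np.ndarray, sample_ids: list, loo_y: np.ndarray | None = None
    ) -> SampleStatMatrix:
        gene_idx = np.arange(len(self.gene_ids_))[:, None]
        c1 = self.counts_[0][gene_idx, calls].T.astype(float)  # samples x genes
        c2 = self.counts_[1][gene_idx, calls].T.astype(float)
        n1 = np.full(c1.shape[0], float(self.n_[0]))
        n2 = np.full(c1.shape[0], float(self.n_[1]))
        if loo_y is not None:
            c1[loo_y == 0] -= 1
            c2[loo_y == 1] -= 1
            n1[loo_y == 0] -= 1
            n2[loo_y == 1] -= 1
        n1, n2 = n1[:, None], n2[:, None]
        # pseudo-count of 1 on both counts and denominators when either is 0
        zero = (c1 == 0) | (c2 == 0)
        p1 = np.where(zero, (c1 + 1) / (n1 + 1), c1 / n1)
        p2 = np.where(zero, (c2 + 1) / (n2 + 1), c2 / n2)
        return SampleStatMatrix(sample_ids, list(self.gene_ids_), np.log(p1 / p2))


def genotype_correlation_stats(
    geno: GenotypeMatrix, labels: PhenotypeLabels
) -> SampleStatMatrix:
    """Genotype-frequency log-ratio statistics for a cohort against itself."""
    return GenotypeProfiles().fit(geno, labels).score_training()


# ---------------------------------------------------------------------------
# Weighted KS enrichment

def sample_enrichment_score(
    stats: np.ndarray,
    member_mask: np.ndarray,
    p: float = 1.0,
) -> float:
    """Weighted KS enrichment score for a single sample and gene set.

    ``stats`` holds the sample's correlation statistics in gene order and
    ``member_mask`` flags the set's member genes.  Ranking ties break by
    stable gene order; the returned score is the signed running-sum value of
    maximal absolute deviation (first occurrence on ties).
    """
    stats = np.asarray(stats, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    if stats.shape != member_mask.shape or stats.ndim != 1:
        raise ValueError("stats and member_mask must be 1-D of equal length")
    G = stats.size
    m = int(member_mask.sum())
    if m == 0:
        raise ValueError("gene set has no member among the statistic genes")
    if m == G:
        raise ValueError("gene set covers all genes; non-member step undefined")
    order = np.argsort(-stats, kind="stable")
    w = np.abs(stats[order]) ** p
    mem = member_mask[order]
    msum = w[mem].sum()
    if msum == 0:
        # all member weights vanish; fall back to equal member steps
        steps = np.where(mem, 1.0 / m, -1.0 / (G - m))
    else:
        steps = np.where(mem, w / msum, -1.0 / (G - m))
    run = np.cumsum(steps)
    a = np.abs(run)
    # earliest position within 1e-12 of the extreme: analytic +v/-v ties
    # resolve to the first attained, independent of summation order
    return float(run[np.argmax(a >= a.max() - 1e-12)])


def enrichment_matrix(
    stats: SampleStatMatrix,
    sets: GeneSetCollection,
    p: float = 1.0,
) -> EnrichmentMatrix:
    """Samples x gene-sets matrix of weighted KS enrichment scores.

    The running sum is piecewise linear between member genes, so its signed
    maximal deviation is attained either at a member position or just before
    one; only those 2m candidates are evaluated per set, which keeps the
    cost at O(samples * (G log G + sum_k m_k log m_k)) instead of walking
    all genes for every set.
    """
    gene_pos = {g: i for i, g in enumerate(stats.gene_ids)}
    S = stats.stats
    n, G = S.shape
    order = np.argsort(-S, axis=1, kind="stable")
    inv = np.empty_like(order)
    np.put_along_axis(inv, order, np.arange(G)[None, :].repeat(n, axis=0), axis=1)
    absS = np.abs(S) ** p
    scores = np.empty((n, len(sets)))
    for k, (name, members) in enumerate(sets.sets.items()):
        cols = np.array([gene_pos[g] for g in members if g in gene_pos])
        m = cols.size
        if m == 0:
            raise ValueError(
                f"gene set {name!r} has no member among the statistic genes"
            )
        if m == G:
            raise ValueError(f"gene set {name!r} covers all genes")
        ranks = inv[:, cols]  # (n, m) positions of members in each ranking
        w = absS[:, cols]
        idx = np.argsort(ranks, axis=1)
        r = np.take_along_axis(ranks, idx, axis=1).astype(float)
        wr = np.take_along_axis(w, idx, axis=1)
        msum = wr.sum(axis=1, keepdims=True)
        frac = np.where(msum == 0, 1.0 / m, wr / np.where(msum == 0, 1.0, msum))
        W = np.cumsum(frac, axis=1)
        j = np.arange(1, m + 1, dtype=float)
        miss = 1.0 / (G - m)
        at = W - (r + 1.0 - j) * miss  # value after the j-th member step
        before = np.concatenate(
            [np.zeros((n, 1)), W[:, :-1]], axis=1
        ) - (r - (j - 1.0)) * miss  # value just before the j-th member
        # interleave in walk order; earliest candidate within 1e-12 of the
        # extreme wins, matching the full running sum's first-occurrence rule
        cand = np.empty((n, 2 * m))
        cand[:, 0::2] = before
        cand[:, 1::2] = at
        a = np.abs(cand)
        peak = np.argmax(a >= a.max(axis=1, keepdims=True) - 1e-12, axis=1)
        scores[:, k] = np.take_along_axis(cand, peak[:, None], axis=1)[:, 0]
    return EnrichmentMatrix(
        list(stats.sample_ids), list(sets.set_names), scores, normalized=False,
        meta={"p": p},
    )


# ---------------------------------------------------------------------------
# Permutation normalization

def normalize_enrichment(
    scores: EnrichmentMatrix,
    stats_builder: Callable[[PhenotypeLabels], SampleStatMatrix],
    sets: GeneSetCollection,
    labels: PhenotypeLabels,
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
    pool_samples: bool = False,
) -> EnrichmentMatrix:
    """Normalize scores against label-permutation backgrounds.

    For each (sample, set) cell, the class labels are permuted ``n_perm``
    times (class sizes preserved), statistics and scores are recomputed, and
    the original score is divided by the mean of the same-signed background
    scores for that cell.  With ``pool_samples`` the background means are
    pooled across samples, giving one positive and one negative divisor per
    gene set.  Cells with no same-signed background are left unchanged;
    their count is recorded in ``meta['n_unnormalized']``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n, K = scores.scores.shape
    pos_sum = np.zeros((n, K))
    pos_cnt = np.zeros((n, K), dtype=int)
    neg_sum = np.zeros((n, K))
    neg_cnt = np.zeros((n, K), dtype=int)
    for _ in range(n_perm):
        perm_y = rng.permutation(labels.y)
        perm_labels = PhenotypeLabels(
            list(labels.sample_ids), perm_y, labels.class_names
        )
        bg = enrichment_matrix(stats_builder(perm_labels), sets, p=p).scores
        pos = bg > 0
        neg = bg < 0
        pos_sum += np.where(pos, bg, 0.0)
        pos_cnt += pos
        neg_sum += np.where(neg, bg, 0.0)
        neg_cnt += neg
    if pool_samples:
        pos_sum = np.broadcast_to(pos_sum.sum(axis=0), (n, K))
        pos_cnt = np.broadcast_to(pos_cnt.sum(axis=0), (n, K))
        neg_sum = np.broadcast_to(neg_sum.sum(axis=0), (n, K))
        neg_cnt = np.broadcast_to(neg_cnt.sum(axis=0), (n, K))
    orig = scores.scores
    out = orig.copy()
    n_unnormalized = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_mean = pos_sum / pos_cnt
        neg_mean = neg_sum / neg_cnt
    take_pos = orig > 0
    take_neg = orig < 0
    ok_pos = take_pos & (pos_cnt > 0)
    ok_neg = take_neg & (neg_cnt > 0)
    out[ok_pos] = orig[ok_pos] / pos_mean[ok_pos]
    out[ok_neg] = orig[ok_neg] / np.abs(neg_mean[ok_neg])
    n_unnormalized = int((take_pos & ~ok_pos).sum() + (take_neg & ~ok_neg).sum())
    if n_unnormalized:
        logger.warning(
            "%d enrichment cells had no same-signed background and were left "
            "unchanged", n_unnormalized,
        )
    meta = dict(scores.meta)
    meta.update({"n_perm": n_perm, "seed": seed, "n_unnormalized": n_unnormalized})
    return EnrichmentMatrix(
        list(scores.sample_ids), list(scores.set_names), out,
        normalized=True, meta=meta,
    )
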