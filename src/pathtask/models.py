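"""Predictive models over enrichment-score features.

Six model families share one soft-margin SVM core (solved through libsvm
with a precomputed Gram matrix):

* single-task: one linear SVM per data type;
* concatenated: one linear SVM over all tasks' samples stacked as rows;
* multi-task: one SVM with the task-coupling kernel
  K[s,t] = (1/mu + [task_s == task_t]) * <x_s, x_t>, decomposed afterwards
  into per-task effects v_t and a common effect w0 = (1/(mu*T)) * sum_t v_t;
* summed prediction / summed enrichment score / merged: matched-sample
  integrations of the above.

Per-gene-set weights come from the dual expansion w = sum_i alpha_i y_i x_i
(any constant factor only rescales weights and cannot change rankings).
Class C1 is encoded +1; decision values > 0 predict C1, and an exact zero
breaks to C1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .types import EnrichmentMatrix, PhenotypeLabels

__all__ = [
    "TaskDataset",
    "TrainedSvm",
    "MultiTaskModel",
    "GeneSetRanking",
    "linear_gram",
    "multitask_gram",
    "train_svm",
    "weights_single",
    "fit_single_task",
    "fit_concatenated",
    "fit_multitask",
    "summed_prediction",
    "fit_summed_es",
    "fit_merged",
    "rank_gene_sets",
    "predict_classes",
    "loo_cross_validate",
    "LooResult",
]

logger = logging.getLogger(__name__)

DUAL_TOL = 1e-6


@dataclass
class TaskDataset:
    """One task: enrichment-score features plus phenotype labels."""

    task_id: str
    features: EnrichmentMatrix
    labels: PhenotypeLabels

    def __post_init__(self):
        if list(self.features.sample_ids) != list(self.labels.sample_ids):
            raise ValueError(
                f"task {self.task_id!r}: feature and label sample ids differ"
            )

    @property
    def X(self) -> np.ndarray:
        return self.features.scores

    @property
    def y_signed(self) -> np.ndarray:
        return self.labels.signed()


@dataclass
class TrainedSvm:
    """Linear SVM in enrichment-score space."""

    alphas: np.ndarray
    bias: float
    C: float
    w: np.ndarray
    set_names: list
    meta: dict = field(default_factory=dict)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_classes(self.decision(X))


@dataclass
class MultiTaskModel:
    """Multi-task SVM with task-coupling kernel.

    ``v`` holds the task-specific effects (T x K), ``w0`` the common effect,
    and per-task final weights are ``w0 + v_t``.
    """

    alphas: np.ndarray
    bias: float
    C: float
    mu: float
    task_ids: list
    v: np.ndarray
    w0: np.ndarray
    set_names: list
    meta: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return self.w0[None, :] + self.v

    def decision(self, X: np.ndarray, task_id: str) -> np.ndarray:
        if task_id not in self.task_ids:
            raise ValueError(f"unknown task {task_id!r}; fitted on {self.task_ids}")
        t = self.task_ids.index(task_id)
        # kernel expansion: (1/mu) sum_t' v_t' + v_t
        w_eff = self.v.sum(axis=0) / self.mu + self.v[t]
        return np.asarray(X) @ w_eff + self.bias

    def predict(self, X: np.ndarray, task_id: str) -> np.ndarray:
        return predict_classes(self.decision(X, task_id))


@dataclass
class GeneSetRanking:
    """Gene sets ordered by weight; rank 1 is the most important set."""

    entries: list  # of (set_name, weight, rank)

    def rank_of(self, set_name: str) -> int:
        for name, _, rank in self.entries:
            if name == set_name:
                return rank
        raise KeyError(set_name)


# ---------------------------------------------------------------------------
# Kernels

def linear_gram(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    return X @ X.T


def multitask_gram(X: np.ndarray, task_index: np.ndarray, mu: float) -> np.ndarray:
    """Task-coupling linear kernel (1/mu + delta_st) * <x_s, x_t>."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    task_index = np.asarray(task_index)
    same = task_index[:, None] == task_index[None, :]
    return (1.0 / mu + same) * linear_gram(X)


# ---------------------------------------------------------------------------
# Dual solver

def train_svm(gram: np.ndarray, y: np.ndarray, C: float, tol: float = DUAL_TOL):
    """Solve the soft-margin SVM dual on a precomputed Gram matrix.

    Returns ``(alphas, bias)`` with alphas of full sample length
    (0 <= alpha_i <= C, sum alpha_i y_i = 0 within solver tolerance).
    """
    gram = np.asarray(gram, dtype=float)
    gram = 0.5 * (gram + gram.T)  # defensive symmetrization
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("labels must be +1/-1")
    if C <= 0:
        raise ValueError("C must be > 0")
    svc = SVC(C=C, kernel="precomputed", tol=tol, cache_size=500,
              max_iter=10_000_000)
    svc.fit(gram, y)
    alphas = np.zeros(len(y))
    alphas[svc.support_] = svc.dual_coef_[0] * y[svc.support_]
    alphas = np.clip(alphas, 0.0, C)
    residual = abs(float(alphas @ y))
    if residual > 1e-4:
        raise RuntimeError(
            f"SVM dual did not converge: |sum alpha_i y_i| = {residual:.2e}"
        )
    return alphas, float(svc.intercept_[0])


def weights_single(alphas: np.ndarray, y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-gene-set weights from the dual expansion, w = sum_i alpha_i y_i x_i."""
    return (np.asarray(alphas) * np.asarray(y)) @ np.asarray(X)


# ---------------------------------------------------------------------------
# Model fits

def fit_single_task(task: TaskDataset, C: float = 1.0) -> TrainedSvm:
    """Standard linear SVM on one task's enrichment scores."""
    X, y = task.X, task.y_signed
    alphas, bias = train_svm(linear_gram(X), y, C)
    w = weights_single(alphas, y, X)
    return TrainedSvm(
        alphas, bias, C, w, list(task.features.set_names),
        meta={"kernel": "linear", "task_id": task.task_id},
    )


def _check_shared_sets(tasks: Sequence[TaskDataset]) -> list:
    if not tasks:
        raise ValueError("need at least one task")
    ref = list(tasks[0].features.set_names)
    for t in tasks[1:]:
        if list(t.features.set_names) != ref:
            raise ValueError(
                f"task {t.task_id!r} has different gene-set features than "
                f"{tasks[0].task_id!r}"
            )
    return ref


def fit_concatenated(tasks: Sequence[TaskDataset], C: float = 1.0) -> TrainedSvm:
    """One linear SVM over all tasks' samples stacked as rows."""
    set_names = _check_shared_sets(tasks)
    X = np.vstack([t.X for t in tasks])
    y = np.concatenate([t.y_signed for t in tasks])
    alphas, bias = train_svm(linear_gram(X), y, C)
    w = weights_single(alphas, y, X)
    return TrainedSvm(
        alphas, bias, C, w, set_names,
        meta={"kernel": "linear", "tasks": [t.task_id for t in tasks]},
    )


def fit_multitask(
    tasks: Sequence[TaskDataset], C: float = 1.0, mu: float = 1.0
) -> MultiTaskModel:
    """Multi-task SVM with the task-coupling kernel."""
    set_names = _check_shared_sets(tasks)
    X = np.vstack([t.X for t in tasks])
    y = np.concatenate([t.y_signed for t in tasks])
    task_index = np.concatenate(
        [np.full(t.X.shape[0], i) for i, t in enumerate(tasks)]
    )
    alphas, bias = train_svm(multitask_gram(X, task_index, mu), y, C)
    T = len(tasks)
    v = np.stack(
        [weights_single(alphas[task_index == i], y[task_index == i],
                        X[task_index == i]) for i in range(T)]
    )
    w0 = v.sum(axis=0) / (mu * T)
    return MultiTaskModel(
        alphas, bias, C, mu, [t.task_id for t in tasks], v, w0, set_names,
        meta={"kernel": "multitask"},
    )


def summed_prediction(
    models: Sequence[TrainedSvm], features_per_task: Sequence[np.ndarray]
) -> np.ndarray:
    """Matched-sample class prediction from summed single-task decision values."""
    if len(models) != len(features_per_task):
        raise ValueError("one feature matrix per model required")
    total = sum(m.decision(X) for m, X in zip(models, features_per_task))
    return predict_classes(total)


def fit_summed_es(tasks: Sequence[TaskDataset], C: float = 1.0) -> TrainedSvm:
    """Single-task SVM on element-wise summed enrichment scores (matched samples)."""
    set_names = _check_shared_sets(tasks)
    for t in tasks[1:]:
        if list(t.features.sample_ids) != list(tasks[0].features.sample_ids):
            raise ValueError("summed-ES model needs matched samples across tasks")
    X = sum(t.X for t in tasks)
    if np.allclose(X, 0.0):
        raise ValueError("summed enrichment scores are identically zero; degenerate input")
    y = tasks[0].y_signed
    alphas, bias = train_svm(linear_gram(X), y, C)
    w = weights_single(alphas, y, X)
    return TrainedSvm(
        alphas, bias, C, w, set_names,
        meta={"kernel": "linear", "model": "summed_es", "tasks": [t.task_id for t in tasks]},
    )


def fit_merged(tasks: Sequence[TaskDataset], C: float = 1.0) -> TrainedSvm:
    """Single SVM on per-sample concatenation of all tasks' enrichment scores.

    The fitted weight vector has one block per task; ``meta['blocks']`` maps
    task ids to their block, and ``meta['combined_w']`` holds the per-set sum
    over blocks used for ranking.
    """
    set_names = _check_shared_sets(tasks)
    for t in tasks[1:]:
        if list(t.features.sample_ids) != list(tasks[0].features.sample_ids):
            raise ValueError("merged model needs matched samples across tasks")
    X = np.hstack([t.X for t in tasks])
    y = tasks[0].y_signed
    alphas, bias = train_svm(linear_gram(X), y, C)
    w = weights_single(alphas, y, X)
    K = len(set_names)
    blocks = {t.task_id: w[i * K:(i + 1) * K] for i, t in enumerate(tasks)}
    combined = sum(blocks.values())
    model = TrainedSvm(
        alphas, bias, C, w,
        [f"{t.task_id}:{s}" for t in tasks for s in set_names],
        meta={"kernel": "linear", "model": "merged",
              "tasks": [t.task_id for t in tasks]},
    )
    model.meta["blocks"] = blocks
    model.meta["combined_w"] = combined
    model.meta["base_set_names"] = set_names
    return model


# ---------------------------------------------------------------------------
# Rankings and prediction helpers

def rank_gene_sets(
    w: np.ndarray, set_names: Sequence[str], signed: bool = False
) -> GeneSetRanking:
    """Rank gene sets by decreasing |w| (or signed w), ties by set name."""
    w = np.asarray(w, dtype=float)
    if len(w) != len(set_names):
        raise ValueError("weight vector length does not match set names")
    key = w if signed else np.abs(w)
    order = sorted(range(len(w)), key=lambda i: (-key[i], set_names[i]))
    entries = [(set_names[i], float(w[i]), rank + 1) for rank, i in enumerate(order)]
    return GeneSetRanking(entries)


def predict_classes(decision: np.ndarray) -> np.ndarray:
    """Map decision values to class indices: > 0 -> C1 (0), < 0 -> C2 (1).

    An exact zero breaks to C1 (logged).
    """
    decision = np.asarray(decision, dtype=float)
    n_ties = int((decision == 0).sum())
    if n_ties:
        logger.info("%d decision value(s) exactly zero; tie-break to C1", n_ties)
    return np.where(decision >= 0, 0, 1)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation

@dataclass
class LooResult:
    predictions: np.ndarray  # class indices, 0 = C1
    truth: np.ndarray
    accuracy: float
    ppv: float  # nan when no positive predictions
    npv: float  # nan when no negative predictions
    confusion: dict


def loo_cross_validate(
    build_and_predict: Callable[[np.ndarray, int], int],
    labels: PhenotypeLabels,
) -> LooResult:
    """Leave-one-out evaluation.

    ``build_and_predict(train_idx, test_idx)`` refits the whole pipeline on
    the training indices (so enrichment statistics can be recomputed without
    the held-out sample) and returns the held-out sample's predicted class
    index.  C1 is the positive class for PPV/NPV.
    """
    n = labels.n_samples
    preds = np.empty(n, dtype=int)
    all_idx = np.arange(n)
    for i in range(n):
        preds[i] = build_and_predict(np.delete(all_idx, i), i)
    truth = labels.y
    tp = int(((preds == 0) & (truth == 0)).sum())
    fp = int(((preds == 0) & (truth == 1)).sum())
    tn = int(((preds == 1) & (truth == 1)).sum())
    fn = int(((preds == 1) & (truth == 0)).sum())
    accuracy = (tp + tn) / n
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return LooResult(
        preds, truth.copy(), accuracy, ppv, npv,
        {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
    )
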