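"""Simulation studies: repeated generate -> enrich -> fit -> predict cycles.

Four studies are provided:

* task-similarity: five scenarios trading off shared versus task-specific
  gene-set signal, six models, accuracy per data type / matched sample;
* sample-size: scenario 3 with the training-cohort size swept;
* task-count: expression (or genotype) task collections with a varying
  number of tasks in the multi-task model;
* rank recovery: how highly each model's weights rank the one gene set
  that carries both expression and genotype signal.

Every study is a pure function of (parameters, seed); means and standard
errors are computed over replicate-level metrics (se = sd / sqrt(reps)).
Default replicate counts are scaled down from exhaustive runs (accuracy
studies 50, rank study 100); flags restore any scale.  Enrichment scores
are not permutation-normalized inside the studies.  Test samples are always
scored against the training cohort's class profiles, so test labels never
touch the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GaussianProfiles, GenotypeProfiles, enrichment_matrix
from .models import (
    TaskDataset,
    fit_concatenated,
    fit_merged,
    fit_multitask,
    fit_single_task,
    fit_summed_es,
    rank_gene_sets,
    summed_prediction,
)
from .simulate import (
    RANK_SPEC,
    SCENARIO_TABLE,
    ScenarioSpec,
    SimParams,
    SimulatedTask,
    build_scenario,
    build_task_collection,
)

__all__ = [
    "ExperimentResult",
    "enrich_scenario",
    "run_similarity_experiment",
    "run_sample_size_experiment",
    "run_task_count_experiment",
    "run_rank_experiment",
    "summarize",
]

ACCURACY_MODELS = (
    "single_task", "multi_task", "concatenated",
    "summed_prediction", "summed_es", "merged",
)
RANK_WEIGHTS = (
    "single_task_expression", "single_task_genotype", "single_task_summed",
    "multi_task_common", "concatenated", "summed_es", "merged_summed",
)


@dataclass
class ExperimentResult:
    """Per-condition mean metrics with standard errors over replicates."""

    experiment: str
    table: pd.DataFrame  # columns: condition, model, metric, mean, se, reps
    seed: int
    replicates: int
    meta: dict = field(default_factory=dict)

    def lookup(self, condition, model, metric) -> tuple:
        t = self.table
        row = t[(t.condition == condition) & (t.model == model) & (t.metric == metric)]
        if len(row) != 1:
            raise KeyError((condition, model, metric))
        return float(row["mean"].iloc[0]), float(row["se"].iloc[0])


def _aggregate(experiment, rows, seed, reps, meta=None) -> ExperimentResult:
    """rows: list of (condition, model, metric, replicate_value)."""
    df = pd.DataFrame(rows, columns=["condition", "model", "metric", "value"])
    agg = (
        df.groupby(["condition", "model", "metric"], sort=False)["value"]
        .agg(["mean", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
              "count"])
        .reset_index()
    )
    agg.columns = ["condition", "model", "metric", "mean", "se", "reps"]
    return ExperimentResult(experiment, agg, seed, reps, meta or {})


# ---------------------------------------------------------------------------
# Shared per-replicate pipeline

def enrich_scenario(data: SimulatedTask, p: float = 1.0) -> dict:
    """Enrichment-score features for both tasks, train and test cohorts."""
    eprof = GaussianProfiles().fit(data.expr_train, data.labels_train)
    gprof = GenotypeProfiles().fit(data.geno_train, data.labels_train)
    out = {
        "expr_train": enrichment_matrix(eprof.score_training(), data.sets, p=p),
        "geno_train": enrichment_matrix(gprof.score_training(), data.sets, p=p),
        "expr_test": enrichment_matrix(eprof.score(data.expr_test), data.sets, p=p),
        "geno_test": enrichment_matrix(gprof.score(data.geno_test), data.sets, p=p),
    }
    return out


def _fit_all(es: dict, data: SimulatedTask, C: float, mu: float) -> dict:
    tasks = [
        TaskDataset("expression", es["expr_train"], data.labels_train),
        TaskDataset("genotype", es["geno_train"], data.labels_train),
    ]
    single_e = fit_single_task(tasks[0], C)
    single_g = fit_single_task(tasks[1], C)
    return {
        "tasks": tasks,
        "single": {"expression": single_e, "genotype": single_g},
        "multi": fit_multitask(tasks, C, mu),
        "concat": fit_concatenated(tasks, C),
        "summed_es": fit_summed_es(tasks, C),
        "merged": fit_merged(tasks, C),
    }


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float((pred == truth).mean())


def _scenario_replicate_accuracies(
    data: SimulatedTask, C: float, mu: float
) -> dict:
    es = enrich_scenario(data)
    fits = _fit_all(es, data, C, mu)
    Xe, Xg = es["expr_test"].scores, es["geno_test"].scores
    truth = data.labels_test.y
    acc = {}
    for dtype, X in (("expression", Xe), ("genotype", Xg)):
        acc[("single_task", dtype)] = _accuracy(fits["single"][dtype].predict(X), truth)
        acc[("multi_task", dtype)] = _accuracy(fits["multi"].predict(X, dtype), truth)
        acc[("concatenated", dtype)] = _accuracy(fits["concat"].predict(X), truth)
    matched_pred = summed_prediction(
        [fits["single"]["expression"], fits["single"]["genotype"]], [Xe, Xg]
    )
    acc[("summed_prediction", "matched")] = _accuracy(matched_pred, truth)
    acc[("summed_es", "matched")] = _accuracy(fits["summed_es"].predict(Xe + Xg), truth)
    acc[("merged", "matched")] = _accuracy(
        fits["merged"].predict(np.hstack([Xe, Xg])), truth
    )
    return acc


# ---------------------------------------------------------------------------
# Studies

def run_similarity_experiment(
    params: SimParams | None = None,
    scenarios=(1, 2, 3, 4, 5),
    n_train: int = 50,
    n_test: int = 50,
    reps: int = 50,
    seed: int = 0,
    C: float = 1.0,
    mu: float = 1.0,
) -> ExperimentResult:
    """Accuracy of all six models across the task-similarity scenarios."""
    params = params or SimParams()
    rows = []
    ss = np.random.SeedSequence(seed)
    for scen in scenarios:
        spec = SCENARIO_TABLE[scen] if isinstance(scen, int) else scen
        name = f"scenario{scen}" if isinstance(scen, int) else str(spec.counts)
        for rep_seed in ss.spawn(reps):
            rng = np.random.default_rng(rep_seed)
            data = build_scenario(spec, params, n_train, n_test, rng)
            acc = _scenario_replicate_accuracies(data, C, mu)
            for (model, dtype), value in acc.items():
                rows.append((name, model, f"accuracy_{dtype}", value))
    return _aggregate(
        "similarity", rows, seed, reps,
        {"n_train": n_train, "n_test": n_test, "C": C, "mu": mu},
    )


def run_sample_size_experiment(
    params: SimParams | None = None,
    scenario: int = 3,
    sizes=(10, 20, 50, 100, 200),
    reps: int = 50,
    seed: int = 0,
    C: float = 1.0,
    mu: float = 1.0,
) -> ExperimentResult:
    """Accuracy of all six models as the training-cohort size varies."""
    params = params or SimParams()
    spec = SCENARIO_TABLE[scenario] if isinstance(scenario, int) else scenario
    rows = []
    ss = np.random.SeedSequence(seed)
    for n in sizes:
        for rep_seed in ss.spawn(reps):
            rng = np.random.default_rng(rep_seed)
            data = build_scenario(spec, params, n, n, rng)
            acc = _scenario_replicate_accuracies(data, C, mu)
            for (model, dtype), value in acc.items():
                rows.append((f"n={n}", model, f"accuracy_{dtype}", value))
    return _aggregate(
        "sample_size", rows, seed, reps, {"scenario": scenario, "C": C, "mu": mu},
    )


def _collection_features(task, kind: str, p: float = 1.0):
    if kind == "expression":
        prof = GaussianProfiles().fit(task.train, task.labels_train)
    else:
        prof = GenotypeProfiles().fit(task.train, task.labels_train)
    es_train = enrichment_matrix(prof.score_training(), task.sets, p=p)
    es_test = enrichment_matrix(prof.score(task.test), task.sets, p=p)
    return es_train, es_test


def run_task_count_experiment(
    params: SimParams | None = None,
    T_values=(1, 2, 5, 10, 20, 50, 100),
    reps: int = 10,
    seed: int = 0,
    kind: str = "expression",
    C: float = 1.0,
    mu: float = 1.0,
) -> ExperimentResult:
    """Multi-task accuracy as the number of tasks grows, with a single-task baseline.

    Within a replicate the T-task model uses the first T tasks of one
    collection, so conditions share tasks and differ only in how many are
    coupled.  The single-task baseline is the first task fit alone.
    """
    params = params or SimParams()
    T_max = max(T_values)
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.spawn(reps):
        rng = np.random.default_rng(rep_seed)
        collection = build_task_collection(T_max, params, rng, kind=kind)
        feats = [_collection_features(t, kind) for t in collection]
        datasets = [
            TaskDataset(t.task_id, es_tr, t.labels_train)
            for t, (es_tr, _) in zip(collection, feats)
        ]
        base = fit_single_task(datasets[0], C)
        base_acc = _accuracy(
            base.predict(feats[0][1].scores), collection[0].labels_test.y
        )
        rows.append(("baseline", "single_task", "accuracy", base_acc))
        for T in T_values:
            model = fit_multitask(datasets[:T], C, mu)
            correct, total = 0, 0
            for t, (_, es_te) in zip(collection[:T], feats[:T]):
                pred = model.predict(es_te.scores, t.task_id)
                correct += int((pred == t.labels_test.y).sum())
                total += len(pred)
            rows.append((f"T={T}", "multi_task", "accuracy", correct / total))
    return _aggregate(
        "task_count", rows, seed, reps, {"kind": kind, "C": C, "mu": mu},
    )


def run_rank_experiment(
    params: SimParams | None = None,
    spec: ScenarioSpec = RANK_SPEC,
    n: int = 400,
    reps: int = 100,
    seed: int = 0,
    C: float = 1.0,
    mu: float = 1.0,
) -> ExperimentResult:
    """Mean rank of the target (type-1) gene set under each weight type."""
    params = params or SimParams()
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.spawn(reps):
        rng = np.random.default_rng(rep_seed)
        data = build_scenario(spec, params, n_train=n, n_test=4, rng=rng)
        es = enrich_scenario(data)
        fits = _fit_all(es, data, C, mu)
        target = data.target_set
        set_names = list(data.sets.set_names)
        w_e = fits["single"]["expression"].w
        w_g = fits["single"]["genotype"].w
        weights = {
            "single_task_expression": w_e,
            "single_task_genotype": w_g,
            "single_task_summed": w_e + w_g,
            "multi_task_common": fits["multi"].w0,
            "concatenated": fits["concat"].w,
            "summed_es": fits["summed_es"].w,
            "merged_summed": fits["merged"].meta["combined_w"],
        }
        for label, w in weights.items():
            rank = rank_gene_sets(w, set_names).rank_of(target)
            rows.append(("rank", label, "target_rank", float(rank)))
    return _aggregate(
        "rank_recovery", rows, seed, reps,
        {"spec": spec.counts, "n": n, "C": C, "mu": mu},
    )


# ---------------------------------------------------------------------------
# Reporting

def summarize(results) -> pd.DataFrame:
    """Stack one or more ExperimentResults into a tidy table."""
    if isinstance(results, ExperimentResult):
        results = [results]
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "experiment", r.experiment)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
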