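"""Synthetic matched genotype and expression data.

Generative model
----------------
A balanced case-control cohort is drawn under a per-SNP additive disease
model: each causal SNP has a population minor-allele frequency (HWE), a
heterozygote odds ratio drawn from U[1.1, 1.3] (homozygote odds ratio its
square) and a disease prevalence of 0.02, which together determine distinct
case and control genotype distributions; cases carry every risk allele at
its full marginal enrichment, and the case/control status is the phenotype.
This realizes the additive liability

    eta_i = eta0 + sum_j beta_j g_ij + e_i,       e_i ~ N(0, 1),

with beta_j the log heterozygote odds ratio, at the per-SNP marginal level:
the error and the disease-model randomness decide each sample's class, and
every causal SNP keeps the full class association its odds ratio implies.
An optional relabeling stage (``SimParams.relabel``) instead re-draws the
classes from the joint liability over all causal SNPs; with the small
per-SNP odds ratios used here that second noise layer suppresses most of
the marginal associations the gene-set types are defined by, so it is off
by default (see the methods note).

Gene sets come in four types, 10 genes each:

* type 1 -- differentially expressed AND genetically associated: each gene
  is linked to a liability SNP; expression is x = x0 + gamma * g with
  gamma ~ U[1.0, 1.5] and x0 drawn per set from a multivariate normal
  baseline; the same dosages are emitted as the gene's genotype row.
* type 2 -- differentially expressed only: expression is driven by a latent
  liability SNP exactly as in type 1, but the emitted genotype row is an
  independent background SNP, so the genotype task sees noise.
* type 3 -- genetically associated only: the liability SNP is emitted as
  genotype, but gamma = 0, so expression is pure baseline.
* type 4 -- background: i.i.d. normal expression and background SNPs with
  allele frequencies drawn from Beta(0.1, 0.1).

Everything is a deterministic function of the supplied generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtr

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
)

__all__ = [
    "SimParams",
    "ScenarioSpec",
    "ScenarioData",
    "SimulatedTask",
    "SCENARIO_TABLE",
    "simulate_genotypes_hwe",
    "assign_classes",
    "balanced_subset",
    "simulate_expression",
    "build_scenario",
    "build_task_collection",
]


@dataclass
class SimParams:
    """Simulation distributions; defaults are the study conditions.

    ``causal_maf_range`` and the exchangeable multivariate-normal baseline
    (mean 0, unit variance, correlation ``baseline_rho``) substitute for
    cohort-estimated quantities and are fully configurable.
    """

    genes_per_set: int = 10
    or_range: tuple = (1.1, 1.3)
    prevalence: float = 0.02
    causal_maf_range: tuple = (0.05, 0.5)
    background_maf_beta: tuple = (0.1, 0.1)
    # gene-level rows must be representable by a MAF > 0.05 SNP, so the
    # U-shaped background frequency draw is truncated to this band
    background_maf_bounds: tuple = (0.05, 0.95)
    effect_range: tuple = (1.0, 1.5)
    baseline_mean: float = 0.0
    baseline_var: float = 1.0
    baseline_rho: float = 0.2
    background_mean: float = 0.0
    background_sd: float = 1.0
    relabel: str = "none"  # or "liability" / "logistic" / "probit"
    max_draw_factor: int = 200

    def __post_init__(self):
        if not (1.0 < self.or_range[0] <= self.or_range[1]):
            raise ValueError("odds-ratio range must lie in (1, inf)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (-1.0 / (self.genes_per_set - 1) < self.baseline_rho <= 1.0):
            raise ValueError("baseline correlation makes the covariance non-PSD")
        if self.relabel not in ("none", "liability", "logistic", "probit"):
            raise ValueError(
                "relabel must be 'none', 'liability', 'logistic' or 'probit'"
            )

    def baseline_cholesky(self) -> np.ndarray:
        g = self.genes_per_set
        cov = self.baseline_var * (
            (1 - self.baseline_rho) * np.eye(g) + self.baseline_rho * np.ones((g, g))
        )
        return np.linalg.cholesky(cov)


@dataclass
class ScenarioSpec:
    """Counts of the four gene-set types."""

    n_type1: int
    n_type2: int
    n_type3: int
    n_type4: int

    def __post_init__(self):
        for n in (self.n_type1, self.n_type2, self.n_type3, self.n_type4):
            if n < 0:
                raise ValueError("gene-set counts must be >= 0")
        if self.n_sets == 0:
            raise ValueError("need at least one gene set")

    @property
    def n_sets(self) -> int:
        return self.n_type1 + self.n_type2 + self.n_type3 + self.n_type4

    @property
    def counts(self) -> tuple:
        return (self.n_type1, self.n_type2, self.n_type3, self.n_type4)


#: The five task-similarity scenarios (type-1..4 gene-set counts).
SCENARIO_TABLE = {
    1: ScenarioSpec(0, 20, 20, 60),
    2: ScenarioSpec(5, 15, 15, 65),
    3: ScenarioSpec(10, 10, 10, 70),
    4: ScenarioSpec(15, 5, 5, 75),
    5: ScenarioSpec(20, 0, 0, 80),
}

#: Design of the gene-set rank-recovery study: one target set of type 1.
RANK_SPEC = ScenarioSpec(1, 5, 5, 89)


# ---------------------------------------------------------------------------
# Primitive generators

def simulate_genotypes_hwe(
    mafs: Sequence[float], n_samples: int, rng: np.random.Generator,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Independent HWE dosages: P(g) = ((1-f)^2, 2f(1-f), f^2) per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs < 0) | (mafs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    calls = rng.binomial(2, mafs[:, None], size=(len(mafs), n_samples))
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(len(mafs))]
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(list(snp_ids), sample_ids, calls)


def case_control_genotype_distributions(
    freqs: np.ndarray, ors: np.ndarray, prevalence: float
):
    """Genotype distributions of cases and controls per causal SNP.

    Under the additive disease model the disease odds at genotype g are
    o0 * OR^g; the baseline odds o0 are solved (bisection, per SNP) so the
    population disease frequency equals ``prevalence`` at HWE genotype
    frequencies.  Bayes then yields P(g | case) and P(g | control).
    Returns two 3 x N arrays (rows: dosage 0, 1, 2).
    """
    f = np.asarray(freqs, dtype=float)
    R = np.asarray(ors, dtype=float)
    q = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2])  # 3 x N
    Rg = np.stack([np.ones_like(R), R, R**2])

    def mean_penetrance(o0):
        pen = o0 * Rg / (1.0 + o0 * Rg)
        return (q * pen).sum(axis=0)

    lo = np.full(f.shape, 1e-12)
    hi = np.full(f.shape, 1e6)
    for _ in range(200):  # bisection in log-odds space
        mid = np.sqrt(lo * hi)
        high = mean_penetrance(mid) > prevalence
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    o0 = np.sqrt(lo * hi)
    pen = o0 * Rg / (1.0 + o0 * Rg)
    k = (q * pen).sum(axis=0)
    p_case = q * pen / k
    p_ctrl = q * (1.0 - pen) / (1.0 - k)
    return p_case, p_ctrl


def sample_case_control_genotypes(
    status: np.ndarray, p_case: np.ndarray, p_ctrl: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosages (SNPs x samples) given case (True) / control (False) statuses.

    Each SNP is drawn independently from its status-conditional genotype
    distribution, as in PLINK-style case-control simulation.
    """
    status = np.asarray(status, dtype=bool)
    n_snps = p_case.shape[1]
    probs = np.where(status[None, None, :], p_case[..., None], p_ctrl[..., None])
    cum0 = probs[0]
    cum1 = probs[0] + probs[1]
    u = rng.random((n_snps, status.size))
    return (u > cum0).astype(int) + (u > cum1).astype(int)


def assign_classes(
    causal_dosages: np.ndarray,
    betas: Sequence[float],
    rng: np.random.Generator,
    link: str = "liability",
) -> np.ndarray:
    """Draw class indices (0 = C1, the disease class) from the liability model.

    The liability is the centered genetic burden plus a standard-normal
    error e_i.  Under the default ``liability`` link the error is the
    assignment randomness itself: a sample joins C1 when its liability
    exceeds zero, so P(C1 | g) = Phi(centered burden) -- the classical
    liability-threshold model.  The ``logistic`` and ``probit`` links
    instead squash the liability (error included) into a probability and
    add an independent Bernoulli draw, which smears the class signal with a
    second noise layer.  ``causal_dosages`` is SNPs x samples; centering on
    the cohort keeps the classes near-balanced.
    """
    causal_dosages = np.asarray(causal_dosages)
    betas = np.asarray(betas, dtype=float)
    if causal_dosages.shape[0] != betas.size:
        raise ValueError("one beta per causal SNP required")
    burden = causal_dosages.T @ betas
    eta = (burden - burden.mean()) + rng.standard_normal(causal_dosages.shape[1])
    if link == "liability":
        return np.where(eta > 0, 0, 1)
    p1 = expit(eta) if link == "logistic" else ndtr(eta)
    return np.where(rng.random(p1.size) < p1, 0, 1)


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, size: int, bounds: tuple
) -> np.ndarray:
    """Rejection-sample Beta(a, b) restricted to ``bounds``."""
    lo, hi = bounds
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.beta(a, b, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.where(need)[0][ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def balanced_subset(y: np.ndarray, n_per_class: int) -> np.ndarray:
    """Indices of the first ``n_per_class`` samples of each class, interleaved order."""
    idx0 = np.where(y == 0)[0]
    idx1 = np.where(y == 1)[0]
    if len(idx0) < n_per_class or len(idx1) < n_per_class:
        raise ValueError(
            f"pool holds {len(idx0)}/{len(idx1)} samples per class, "
            f"need {n_per_class} each"
        )
    return np.sort(np.concatenate([idx0[:n_per_class], idx1[:n_per_class]]))


def simulate_expression(
    baseline: np.ndarray, gammas: np.ndarray, dosages: np.ndarray
) -> np.ndarray:
    """Additive genotype effect on expression: x = x0 + gamma * g (genes x samples)."""
    return baseline + np.asarray(gammas)[:, None] * dosages


# ---------------------------------------------------------------------------
# Scenario construction

@dataclass
class SimulatedTask:
    """Matched train/test data for one simulated cohort."""

    expr_train: ExpressionMatrix
    geno_train: GenotypeMatrix
    labels_train: PhenotypeLabels
    expr_test: ExpressionMatrix
    geno_test: GenotypeMatrix
    labels_test: PhenotypeLabels
    sets: GeneSetCollection
    set_types: dict = field(default_factory=dict)  # set name -> 1..4

    @property
    def target_set(self) -> str:
        """The (first) type-1 set, if any."""
        for name, t in self.set_types.items():
            if t == 1:
                return name
        raise ValueError("no type-1 gene set in this scenario")


ScenarioData = SimulatedTask  # alias: a scenario yields one matched cohort pair


@dataclass
class _ScenarioLaw:
    """Frozen per-replicate parameters shared by train and test draws."""

    spec: ScenarioSpec
    params: SimParams
    set_names: list
    set_types: dict
    gene_ids: list
    gene_type: np.ndarray  # per gene, 1..4
    liab_maf: np.ndarray  # one causal/latent SNP per type-1/2/3 gene
    liab_beta: np.ndarray
    gammas: np.ndarray  # per gene (0 outside types 1-2)
    liab_gene_rows: np.ndarray  # gene index per liability SNP


def _draw_scenario_law(
    spec: ScenarioSpec, params: SimParams, rng: np.random.Generator
) -> _ScenarioLaw:
    g = params.genes_per_set
    set_names, set_types, gene_type = [], {}, []
    for t, count in zip((1, 2, 3, 4), spec.counts):
        for k in range(count):
            name = f"SET_T{t}_{k + 1:03d}"
            set_names.append(name)
            set_types[name] = t
            gene_type.extend([t] * g)
    gene_type = np.array(gene_type)
    # group genes per set in declaration order
    gene_ids = [f"gene{i + 1:05d}" for i in range(spec.n_sets * g)]
    liab_gene_rows = np.where(np.isin(gene_type, (1, 2, 3)))[0]
    n_liab = liab_gene_rows.size
    liab_maf = rng.uniform(*params.causal_maf_range, size=n_liab)
    ors = rng.uniform(*params.or_range, size=n_liab)
    gammas = np.zeros(len(gene_ids))
    de_rows = np.isin(gene_type, (1, 2))
    gammas[de_rows] = rng.uniform(*params.effect_range, size=int(de_rows.sum()))
    return _ScenarioLaw(
        spec, params, set_names, set_types, gene_ids, gene_type,
        liab_maf, np.log(ors), gammas, liab_gene_rows,
    )


def _draw_cohort(
    law: _ScenarioLaw, n_per_class: int, rng: np.random.Generator, prefix: str
):
    """One balanced cohort from a frozen scenario law."""
    params = law.params
    n_needed = 2 * n_per_class
    if law.liab_maf.size:
        p_case, p_ctrl = case_control_genotype_distributions(
            law.liab_maf, np.exp(law.liab_beta), params.prevalence
        )
    if params.relabel == "none":
        # phenotype = case/control status; exactly balanced by construction
        y = np.repeat([0, 1], n_per_class)
        if law.liab_maf.size:
            liab_calls = sample_case_control_genotypes(y == 0, p_case, p_ctrl, rng)
        else:
            liab_calls = np.empty((0, n_needed), dtype=int)
    else:
        # re-draw classes from the joint liability, then fill quotas
        pool = max(2 * n_needed, n_needed + 40)
        liab_calls = np.empty((law.liab_maf.size, 0), dtype=int)
        y_pool = np.empty(0, dtype=int)
        for _ in range(params.max_draw_factor):
            status = np.arange(pool) % 2 == 0
            if law.liab_maf.size:
                draw = sample_case_control_genotypes(status, p_case, p_ctrl, rng)
            else:
                draw = np.empty((0, pool), dtype=int)
            y_new = assign_classes(draw, law.liab_beta, rng, link=params.relabel)
            liab_calls = np.hstack([liab_calls, draw])
            y_pool = np.concatenate([y_pool, y_new])
            if min((y_pool == 0).sum(), (y_pool == 1).sum()) >= n_per_class:
                break
        else:
            raise RuntimeError(
                f"could not reach {n_per_class} samples per class within the "
                "draw budget"
            )
        keep = balanced_subset(y_pool, n_per_class)
        liab_calls = liab_calls[:, keep]
        y = y_pool[keep]
    n = n_needed
    sample_ids = [f"{prefix}{i + 1}" for i in range(n)]

    n_genes = len(law.gene_ids)
    g = params.genes_per_set
    chol = params.baseline_cholesky()

    expr = np.empty((n_genes, n))
    geno = np.zeros((n_genes, n), dtype=int)
    liab_of_gene = {int(r): j for j, r in enumerate(law.liab_gene_rows)}
    bg_rows = []
    for s, name in enumerate(law.set_names):
        t = law.set_types[name]
        rows = np.arange(s * g, (s + 1) * g)
        if t == 4:
            expr[rows] = rng.normal(
                params.background_mean, params.background_sd, size=(g, n)
            )
            bg_rows.extend(rows)
            continue
        z = rng.standard_normal((n, g))
        baseline = (params.baseline_mean + z @ chol.T).T  # genes x samples
        dos = liab_calls[[liab_of_gene[int(r)] for r in rows]]
        expr[rows] = simulate_expression(baseline, law.gammas[rows], dos)
        if t in (1, 3):
            geno[rows] = dos
        else:  # type 2: emitted genotype is an independent background SNP
            bg_rows.extend(rows)
    if bg_rows:
        bg_rows = np.array(bg_rows)
        freqs = _truncated_beta(
            rng, *params.background_maf_beta, bg_rows.size,
            params.background_maf_bounds,
        )
        geno[bg_rows] = rng.binomial(2, freqs[:, None], size=(bg_rows.size, n))

    labels = PhenotypeLabels(sample_ids, y)
    expr_m = ExpressionMatrix(list(law.gene_ids), sample_ids, expr)
    geno_m = GenotypeMatrix(list(law.gene_ids), sample_ids, geno)
    return expr_m, geno_m, labels


def build_scenario(
    spec: ScenarioSpec | int,
    params: SimParams | None = None,
    n_train: int = 50,
    n_test: int = 50,
    rng: np.random.Generator | int = 0,
) -> SimulatedTask:
    """Matched expression + genotype cohorts (train and test) for one scenario.

    ``n_train``/``n_test`` are total sample counts, evenly split between the
    two classes.  Genotype is emitted at gene level directly (each gene
    carries its linked SNP), so the window-mapping step is bypassed.
    """
    if isinstance(spec, int):
        spec = SCENARIO_TABLE[spec]
    params = params or SimParams()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_train % 2 or n_test % 2:
        raise ValueError("sample counts must be even (balanced classes)")
    law = _draw_scenario_law(spec, params, rng)
    expr_tr, geno_tr, y_tr = _draw_cohort(law, n_train // 2, rng, "tr")
    expr_te, geno_te, y_te = _draw_cohort(law, n_test // 2, rng, "te")
    g = params.genes_per_set
    sets = GeneSetCollection(
        {name: law.gene_ids[s * g:(s + 1) * g] for s, name in enumerate(law.set_names)}
    )
    return SimulatedTask(
        expr_tr, geno_tr, y_tr, expr_te, geno_te, y_te, sets, dict(law.set_types)
    )


# ---------------------------------------------------------------------------
# Task collections (varying number of tasks)

@dataclass
class CollectionTask:
    """One task of a task-collection study: a single data type."""

    task_id: str
    train: ExpressionMatrix | GenotypeMatrix
    labels_train: PhenotypeLabels
    test: ExpressionMatrix | GenotypeMatrix
    labels_test: PhenotypeLabels
    sets: GeneSetCollection
    associated: np.ndarray  # boolean per set


def build_task_collection(
    T: int,
    params: SimParams | None = None,
    rng: np.random.Generator | int = 0,
    kind: str = "expression",
    n_train: int = 20,
    n_test: int = 20,
    n_sets: int = 100,
    n_shared_assoc: int = 30,
    n_shared_bg: int = 20,
    n_free_assoc: int = 30,
) -> list:
    """Tasks with partially shared phenotype-associated gene sets.

    Every task marks sets 1..30 associated and 31..50 background; of sets
    51..100 a per-task random 30 are associated.  Each task carries its own
    balanced train and test cohorts of one data type.
    """
    if kind not in ("expression", "genotype"):
        raise ValueError("kind must be 'expression' or 'genotype'")
    params = params or SimParams()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_free = n_sets - n_shared_assoc - n_shared_bg
    if n_free < n_free_assoc:
        raise ValueError("free sets fewer than per-task associated quota")
    tasks = []
    for t in range(T):
        assoc = np.zeros(n_sets, dtype=bool)
        assoc[:n_shared_assoc] = True
        free = np.arange(n_shared_assoc + n_shared_bg, n_sets)
        assoc[rng.choice(free, size=n_free_assoc, replace=False)] = True
        n_assoc_sets = int(assoc.sum())
        # express associated sets through the matched-scenario machinery:
        # associated sets behave as type 1, background as type 4
        counts_spec = ScenarioSpec(n_assoc_sets, 0, 0, n_sets - n_assoc_sets)
        law = _draw_scenario_law(counts_spec, params, rng)
        expr_tr, geno_tr, y_tr = _draw_cohort(law, n_train // 2, rng, f"t{t}tr")
        expr_te, geno_te, y_te = _draw_cohort(law, n_test // 2, rng, f"t{t}te")
        # reorder set names so associated/background interleave per the design
        g = params.genes_per_set
        assoc_names = [n for n in law.set_names if law.set_types[n] == 1]
        bg_names = [n for n in law.set_names if law.set_types[n] == 4]
        ai, bi = iter(assoc_names), iter(bg_names)
        ordered = [next(ai) if a else next(bi) for a in assoc]
        sets = GeneSetCollection(
            {
                f"SET_{k + 1:03d}": law.gene_ids[
                    law.set_names.index(n) * g:(law.set_names.index(n) + 1) * g
                ]
                for k, n in enumerate(ordered)
            }
        )
        train, test = (
            (expr_tr, expr_te) if kind == "expression" else (geno_tr, geno_te)
        )
        tasks.append(
            CollectionTask(f"task{t + 1}", train, y_tr, test, y_te, sets, assoc)
        )
    return tasks
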