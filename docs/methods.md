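# Methods

This note documents the models implemented in `pathtask`, the synthetic
data the test-bed generates, the numerical choices made where the design
was genuinely open, and the limits of what the simulations can show.

## Sample-specific enrichment

### Correlation statistics

Both data types are reduced to a per-sample, per-gene statistic `s_ij`
oriented so that positive values mean "more like class C1".

*Expression.* `s_ij` is the log-likelihood ratio of two class-conditional
Gaussian densities with per-gene class means and standard deviations.
Two regularizations keep it well behaved:

* **Variance floor** — class standard deviations are floored at
  `max(sd, 0.2·|mean|, 1e−8)`. Constant or near-constant genes otherwise
  produce unbounded statistics; the 20%-of-mean form follows common
  signal-to-noise regularization practice in gene-set analysis.
* **Leave-self-out** (default on, `leave_self_out=False` to disable) —
  when scoring a training sample, its own class's mean/sd are re-estimated
  without it. Including the sample inflates the fit of every gene to its
  own class and, summed over a whole ranking, makes even pure-noise gene
  sets look class-informative. Standard deviations use the population
  convention (ddof = 0) so the leave-one-out estimate is defined for the
  minimum class size of two.

A nonparametric variant (`method="kde"` /
`KernelDensityProfiles`) replaces the Gaussian densities with per-gene
Gaussian kernel mixtures using Silverman bandwidths; it shares the
leave-self-out logic (the sample's own kernel is removed) and is intended
for moderate cohort sizes.

*Genotype.* After each gene has been collapsed to one representative SNP,
`s_ij = log(p̂_1/p̂_2)` with `p̂_k` the fraction of class-k samples sharing
sample i's genotype at that gene; if either count is zero, both counts and
both denominators receive a pseudo-count of one. The same leave-self-out
logic applies when scoring training cohorts, for the same reason: a sample
always finds itself in its own class's count, and that bias is coherent
across all genes. Test cohorts are scored against the training profiles,
so their statistics are leakage-free by construction.

### SNP-to-gene collapsing

For each gene, candidate SNPs lie in the window running 1,000 bases
(configurable) upstream of the transcription start site to the end of the
transcribed region — strand-aware, since "upstream" is defined relative to
the TSS. Among window SNPs with minor allele frequency above 0.05
(configurable) the one with the largest Pearson chi-square statistic of
the 2 × k class-by-genotype table (no continuity correction; k = observed
genotype categories) represents the gene. Ties break to the smallest
genomic position, then lexicographic SNP id, making the choice
deterministic. Genes with no eligible SNP are dropped rather than imputed,
and downstream gene sets simply see them as unmapped.

### Weighted KS enrichment score

Within each sample, genes are ranked by decreasing `s_ij` (ties broken by
stable gene order). Walking the ranking, member genes of a set add
`|s|^p / Σ_members |s|^p` and non-members subtract `1/(G − m)`; the score
is the running sum's value of maximal absolute deviation, signed. Choices:

* `p = 1` by default (the statistic-weighted form); `p = 0` recovers the
  classical unweighted KS statistic of the membership indicator.
* If all member weights vanish (possible for genotype statistics, which
  take at most three values per gene and are exactly zero when class
  frequencies tie), member steps fall back to the unweighted `1/m` form
  instead of dividing by zero.
* The extremum of the piecewise-linear running sum is attained at a member
  position or immediately before one, so only those `2m` candidates are
  evaluated; this is exact and makes the cost per sample
  `O(G log G + Σ_k m_k log m_k)` rather than `O(G · K)`.
* When the extremum is a tie between a positive and a negative deviation
  of analytically equal magnitude, the earlier position in the walk wins,
  decided with a 1e−12 tolerance so the outcome does not depend on
  floating-point summation order.

Normalization (off by default in the simulation studies) divides each
positive score by the mean of the strictly positive scores obtained under
label permutations of that same (sample, set) cell, and symmetrically for
negative scores; cells with no same-signed background are left unchanged
and counted in the result's metadata. Background means are per
(sample, set) by default; `pool_samples=True` pools them across samples,
giving one divisor per set and sign. Permutations preserve class sizes
and are driven by an explicit seed recorded in the output.

## Predictive models

All six models share one soft-margin SVM core, solved through libsvm
(scikit-learn `SVC`) on a precomputed Gram matrix with tolerance 1e−6;
dual feasibility (`0 ≤ α ≤ C`, `Σ α_i y_i = 0`) is checked after every
fit. Class C1 is encoded +1; a decision value of exactly zero predicts C1
(logged). Defaults `C = 1` and `μ = 1` are recorded in model metadata and
exposed as flags; no value is prescribed by the problem, and rankings are
invariant to the weight scale.

* **Single-task**: linear kernel per data type, weights
  `w = Σ α_i y_i x_i`.
* **Concatenated**: all tasks' samples stacked as rows in the shared
  gene-set feature space; one weight vector.
* **Multi-task**: kernel `(1/μ + δ_st)·⟨x_s, x_t⟩`. Small μ couples the
  tasks (the 1/μ term acts like a shared component); μ → ∞ recovers
  independent per-task fits up to the shared bias/equality constraint.
  Task-specific effects `v_t` come from each task's slice of the dual
  expansion, the common effect is `w0 = (1/(μT)) Σ_t v_t`, and final
  per-task weights are `w0 + v_t` (the identity `w_t − v_t = w0` holds
  exactly by construction). Any constant factor in these formulas only
  rescales weights and cannot change rankings.
* **Matched-sample models**: summed decision values (ties to C1),
  a single-task fit on element-wise summed enrichment scores (identically
  zero sums are rejected as degenerate), and a merged model on the
  per-sample concatenation of all tasks' scores whose weight vector splits
  back into per-task blocks; the per-set ranking weight is the block sum.

Gene sets are ranked by decreasing `|w|` (ties by name; a signed variant
is available): the sign of a weight encodes class direction, not
importance.

Leave-one-out cross-validation takes a callback that refits the entire
pipeline per fold, so enrichment statistics can be recomputed without the
held-out sample (strict mode); reusing full-cohort enrichment is possible
but leaks the held-out label into the class profiles and is documented as
such. PPV/NPV treat C1 as the positive class and are reported as NaN when
undefined.

## Synthetic data

The generator produces matched expression + genotype cohorts with
gene sets of four types (10 genes each): dual-signal (type 1),
expression-only (type 2), genotype-only (type 3), background (type 4).

**Genotypes and phenotype.** Each causal SNP has a population minor-allele
frequency drawn from U[0.05, 0.5] (a configurable substitute for
cohort-derived frequencies), a heterozygote odds ratio from U[1.1, 1.3]
(homozygote = square) and disease prevalence 0.02. Solving the additive
odds model for the baseline penetrance yields distinct case and control
genotype distributions per SNP; a balanced case-control cohort drawn from
them realizes the additive liability
`η = η0 + Σ β_j g_j + e, e ~ N(0,1)` at the marginal level, with the
disease-model randomness and the error term deciding each sample's class.
The case/control status is the phenotype. An optional relabeling stage
(`SimParams.relabel`) re-draws classes from the joint liability over all
causal SNPs (threshold, logistic or probit); it is off by default because
a second noise layer on top of the marginal model suppresses most of the
per-SNP association — at 110 causal SNPs and the default odds ratios only
~0.4 of each SNP's case-control shift survives — which contradicts the
defining property of the "genetically associated" set types.

**Expression.** Genes in associated sets draw a baseline from a
multivariate normal with exchangeable correlation ρ = 0.2, mean 0 and unit
variance per set (documented substitutes for pathway-estimated moments),
plus an additive genotype effect `γ·g` with γ ~ U[1.0, 1.5] for
differentially expressed genes. Background genes are i.i.d. N(0, 1).

**Set types.** Type 1 genes link to causal SNPs whose dosages are emitted
as the gene's genotype row — matched data by construction. Type 2 genes
are driven by *latent* causal SNPs (full disease-model machinery, so the
expression effect is genuinely class-associated) whose dosages are never
emitted; the emitted rows are background SNPs. Type 3 emits causal SNPs
with γ = 0. Type 4 is background in both. Background allele frequencies
follow Beta(0.1, 0.1) truncated to [0.05, 0.95]: gene-level genotype data
can only arise from SNPs passing the MAF > 0.05 representative-SNP rule,
and untruncated draws produce near-monomorphic rows whose three-valued
statistics degenerate (a single rare genotype carries the entire member
weight and the enrichment score becomes a ±0.9 coin flip).

Cohorts are exactly class-balanced; everything is a deterministic function
of the supplied seed.

**Task collections** (for the task-count study) build T single-data-type
tasks over 100 sets each: sets 1–30 associated and 31–50 background in
every task, and a per-task random 30 of sets 51–100 associated — shared
signal up front, task-private signal behind.

## Experiment harness

Every study is a pure function of (parameters, seed); replicate seeds are
spawned from one `SeedSequence`. Metrics are averaged over replicate-level
values and reported with `se = sd/√reps`; orderings between models are
always assessed with two-standard-error bands, never point equality. Test
samples are scored against the training cohort's class profiles, so test
labels never touch the statistics. Default replicate counts are scaled for
practical runtimes (50 for the accuracy studies, 100 for rank recovery,
10 for task counts) and are flags on every runner.

## What the simulations can and cannot show

The default per-SNP effect sizes are weak by design: a marginal
heterozygote odds ratio in [1.1, 1.3] at prevalence 0.02 caps the
case-control dosage shift per SNP at roughly 0.05–0.09, and a short
calculation shows the Bayes-optimal classifier on this generative law
reaches only ~0.73–0.78 even with the true model in hand. Consequently,
with leakage-free enrichment statistics the fitted models sit close to
chance at n = 50, and no pipeline — with or without label leakage — can
deliver high absolute accuracies or near-top target ranks at these effect
sizes; what the
test-bed demonstrates reliably are the *relative* patterns — integrated
weights (summed single-task, multi-task common, concatenated) rank the
dual-signal target set significantly better than the expression
single-task weights, and the null design calibrates all models to 50%.
Larger odds ratios (e.g. U[2, 3]) restore the full qualitative pattern,
including near-top target ranks for every integrated weight; users probing
the framework's behaviour rather than the epidemiological regime should
raise `SimParams.or_range` and `effect_range`.

Other known limitations: SNPs are independent (no linkage disequilibrium
or population structure); phenotypes are strictly binary and balanced;
expression noise is Gaussian with a single exchangeable-correlation
baseline per set, not a real pathway covariance; and missing genotype
calls are rejected rather than imputed.
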