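import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathtask.enrichment import (
    GaussianProfiles,
    GenotypeProfiles,
    KernelDensityProfiles,
    enrichment_matrix,
    expression_correlation_stats,
    genotype_correlation_stats,
    normalize_enrichment,
    sample_enrichment_score,
)
from pathtask.types import (
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
    SampleStatMatrix,
)


def ks_oracle(stats, members, p=1.0):
    """Independent pure-python running-sum oracle."""
    order = sorted(range(len(stats)), key=lambda i: (-stats[i], i))
    member_weight = sum(abs(stats[i]) ** p for i in order if members[i])
    G, m = len(stats), sum(members)
    run, best = 0.0, 0.0
    for i in order:
        if members[i]:
            if member_weight == 0:
                run += 1.0 / m
            else:
                run += abs(stats[i]) ** p / member_weight
        else:
            run -= 1.0 / (G - m)
        if abs(run) > abs(best) + 1e-12:  # earliest wins on analytic ties
            best = run
    return best


class TestExpressionStats:
    def _expr(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{i}" for i in range(values.shape[1])],
            values,
        )

    def test_symmetric_profiles_give_symmetric_stats(self):
        # class means +-1, equal spread: x=0 scores 0, x=1 scores 2
        prof = GaussianProfiles()
        prof.mean_ = np.array([[1.0], [-1.0]])
        prof.sd_ = np.array([[1.0], [1.0]])
        prof.gene_ids_ = ["g0"]
        new = self._expr([[0.0, 1.0]])
        stats = prof.score(new).stats
        assert stats[0, 0] == pytest.approx(0.0)
        assert stats[1, 0] == pytest.approx(2.0)

    def test_identical_class_profiles_score_zero(self, rng):
        # same values in both classes -> identical profiles -> all-zero stats
        block = rng.normal(size=(5, 4))
        expr = self._expr(np.hstack([block, block]))
        labels = PhenotypeLabels(
            list(expr.sample_ids), np.repeat([0, 1], 4)
        )
        stats = GaussianProfiles().fit(expr, labels).score(expr).stats
        np.testing.assert_allclose(stats, 0.0, atol=1e-12)

    def test_variance_floor_keeps_stats_finite(self):
        expr = self._expr([[5.0, 5.0, 5.0, 5.0]])  # constant gene
        labels = PhenotypeLabels(list(expr.sample_ids), np.array([0, 0, 1, 1]))
        stats = GaussianProfiles().fit(expr, labels).score_training().stats
        assert np.all(np.isfinite(stats))

    def test_leave_self_out_excludes_own_value(self):
        expr = self._expr([[0.0, 4.0, 1.0, 1.0, 10.0, 10.0, 10.0, 10.0]])
        labels = PhenotypeLabels(
            list(expr.sample_ids), np.array([0, 0, 0, 0, 1, 1, 1, 1])
        )
        prof = GaussianProfiles().fit(expr, labels)
        loo = prof.score_training(leave_self_out=True).stats
        # manual: scoring s0 (x=0) with own-class mean/sd from (4,1,1)
        own_mean = np.mean([4.0, 1.0, 1.0])
        own_sd = max(np.std([4.0, 1.0, 1.0]), 0.2 * own_mean)
        other_mean, other_sd = 10.0, max(0.0, 0.2 * 10.0, 1e-8)
        expected = (
            -math.log(own_sd) - (0.0 - own_mean) ** 2 / (2 * own_sd**2)
            + math.log(other_sd) + (0.0 - other_mean) ** 2 / (2 * other_sd**2)
        )
        assert loo[0, 0] == pytest.approx(expected)

    def test_class_swap_negates_stats(self, rng):
        expr = self._expr(rng.normal(size=(6, 10)))
        y = np.repeat([0, 1], 5)
        ids = list(expr.sample_ids)
        a = GaussianProfiles().fit(expr, PhenotypeLabels(ids, y))
        b = GaussianProfiles().fit(expr, PhenotypeLabels(ids, 1 - y))
        np.testing.assert_allclose(
            a.score(expr).stats, -b.score(expr).stats, atol=1e-10
        )


class TestKdeVariant:
    def _expr(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            [f"g{i}" for i in range(values.shape[0])],
            [f"s{i}" for i in range(values.shape[1])],
            values,
        )

    def test_identical_class_data_scores_zero(self, rng):
        block = rng.normal(size=(4, 5))
        expr = self._expr(np.hstack([block, block]))
        labels = PhenotypeLabels(list(expr.sample_ids), np.repeat([0, 1], 5))
        stats = KernelDensityProfiles().fit(expr, labels).score(expr).stats
        np.testing.assert_allclose(stats, 0.0, atol=1e-10)

    def test_class_swap_negates_stats(self, rng):
        expr = self._expr(rng.normal(size=(6, 12)))
        y = np.repeat([0, 1], 6)
        ids = list(expr.sample_ids)
        a = KernelDensityProfiles().fit(expr, PhenotypeLabels(ids, y))
        b = KernelDensityProfiles().fit(expr, PhenotypeLabels(ids, 1 - y))
        np.testing.assert_allclose(a.score(expr).stats, -b.score(expr).stats,
                                   atol=1e-10)

    def test_statistic_orients_towards_own_class(self, rng):
        # well-separated classes: samples score positive on C1-like values
        x = np.concatenate([rng.normal(5, 0.5, 10), rng.normal(-5, 0.5, 10)])
        expr = self._expr(x[None, :])
        labels = PhenotypeLabels(list(expr.sample_ids), np.repeat([0, 1], 10))
        stats = expression_correlation_stats(expr, labels, method="kde")
        assert np.all(stats.stats[:10, 0] > 0)
        assert np.all(stats.stats[10:, 0] < 0)

    def test_unknown_method_rejected(self, rng):
        expr = self._expr(rng.normal(size=(2, 6)))
        labels = PhenotypeLabels(list(expr.sample_ids), np.repeat([0, 1], 3))
        with pytest.raises(ValueError, match="method"):
            expression_correlation_stats(expr, labels, method="nope")


class TestGenotypeStats:
    def test_equal_frequencies_score_zero(self):
        calls = np.array([[0, 1, 0, 1]])
        geno = GenotypeMatrix(["g1"], ["a", "b", "c", "d"], calls)
        labels = PhenotypeLabels(["a", "b", "c", "d"], np.array([0, 0, 1, 1]))
        stats = GenotypeProfiles().fit(geno, labels).score(geno).stats
        np.testing.assert_allclose(stats, 0.0, atol=1e-12)

    def test_frequency_ratio_log2(self):
        # class1: 10/20 carry genotype 1; class2: 5/20 -> log 2
        calls = np.concatenate([[1] * 10, [0] * 10, [1] * 5, [0] * 15])
        geno = GenotypeMatrix(
            ["g1"], [f"s{i}" for i in range(40)], calls[None, :]
        )
        labels = PhenotypeLabels(list(geno.sample_ids), np.repeat([0, 1], 20))
        stats = GenotypeProfiles().fit(geno, labels).score(geno).stats
        assert stats[0, 0] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_pseudo_count_rule_log6(self):
        # class1: 5/10 carry genotype; class2: 0/10 -> log((6/11)/(1/11)) = log 6
        calls = np.concatenate([[1] * 5, [0] * 5, [0] * 10])
        geno = GenotypeMatrix(
            ["g1"], [f"s{i}" for i in range(20)], calls[None, :]
        )
        labels = PhenotypeLabels(list(geno.sample_ids), np.repeat([0, 1], 10))
        stats = GenotypeProfiles().fit(geno, labels).score(geno).stats
        assert stats[0, 0] == pytest.approx(math.log(6.0), abs=1e-12)

    def test_class_swap_negates_stats(self, rng):
        calls = rng.integers(0, 3, size=(6, 20))
        geno = GenotypeMatrix(
            [f"g{i}" for i in range(6)], [f"s{i}" for i in range(20)], calls
        )
        y = rng.permutation(np.repeat([0, 1], 10))
        a = genotype_correlation_stats(geno, PhenotypeLabels(list(geno.sample_ids), y))
        b = genotype_correlation_stats(
            geno, PhenotypeLabels(list(geno.sample_ids), 1 - y)
        )
        np.testing.assert_allclose(a.stats, -b.stats, atol=1e-12)

    def test_leave_self_out_removes_self_count(self):
        # sample 0 is the only class-1 carrier of genotype 2
        calls = np.array([[2, 0, 0, 0, 1, 1, 1, 1]])
        geno = GenotypeMatrix(["g1"], [f"s{i}" for i in range(8)], calls)
        labels = PhenotypeLabels(list(geno.sample_ids), np.repeat([0, 1], 4))
        prof = GenotypeProfiles().fit(geno, labels)
        with_self = prof.score_training(leave_self_out=False).stats[0, 0]
        loo = prof.score_training(leave_self_out=True).stats[0, 0]
        assert with_self == pytest.approx(math.log((2 / 5) / (1 / 5)), abs=1e-12)
        # without itself: 0/3 carriers in class1, 0/4 in class2 -> log(1/1) via pseudo
        assert loo == pytest.approx(math.log((1 / 4) / (1 / 5)), abs=1e-12)


class TestEnrichmentScore:
    def test_worked_five_gene_example(self):
        stats = np.array([3.0, 2.0, 1.0, 0.5, 0.1])
        members = np.array([1, 0, 1, 0, 0], dtype=bool)
        assert sample_enrichment_score(stats, members) == pytest.approx(0.75)

    def test_top_half_set_positive_complement_negative(self):
        stats = np.array([1.0, 1.0, 1.0, 1.0])
        top = np.array([1, 1, 0, 0], dtype=bool)
        es_top = sample_enrichment_score(stats, top)
        es_bottom = sample_enrichment_score(stats, ~top)
        assert es_top > 0
        assert es_bottom == pytest.approx(-es_top)

    def test_p_zero_equals_classical_ks_distance(self):
        stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        members = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        # unweighted KS of the membership indicator: max |i/m - j/(G-m)|
        es = sample_enrichment_score(stats, members, p=0.0)
        assert abs(es) == pytest.approx(1.0)  # both members lead the ranking

    def test_errors_on_degenerate_sets(self):
        stats = np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            sample_enrichment_score(stats, np.array([0, 0], dtype=bool))
        with pytest.raises(ValueError):
            sample_enrichment_score(stats, np.array([1, 1], dtype=bool))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raw_scores_bounded_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(5, 21))
        stats = rng.normal(size=G)
        m = int(rng.integers(1, G))
        members = np.zeros(G, dtype=bool)
        members[rng.choice(G, size=m, replace=False)] = True
        es = sample_enrichment_score(stats, members)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert es == pytest.approx(ks_oracle(list(stats), list(members)), abs=1e-12)

    def test_step_masses_sum_to_plus_minus_one(self, rng):
        # bookkeeping: member increments total +1, non-member total -1
        stats = rng.normal(size=15)
        members = np.zeros(15, dtype=bool)
        members[:4] = True
        order = np.argsort(-stats, kind="stable")
        w = np.abs(stats[order])
        mem = members[order]
        member_total = (w[mem] / w[mem].sum()).sum()
        nonmember_total = mem.size - mem.sum()
        assert member_total == pytest.approx(1.0)
        assert (1.0 / (15 - 4)) * nonmember_total == pytest.approx(1.0)

    def test_raising_member_stat_never_lowers_positive_es(self, rng):
        for _ in range(20):
            stats = np.sort(rng.normal(size=12))[::-1].copy()
            members = np.zeros(12, dtype=bool)
            members[rng.choice(12, size=4, replace=False)] = True
            es = sample_enrichment_score(stats, members)
            if es <= 0:
                continue
            # push one member up without crossing its neighbour's rank
            idx = np.where(members)[0][0]
            bumped = stats.copy()
            bumped[idx] += 1e-6
            assert sample_enrichment_score(bumped, members) >= es - 1e-9


class TestEnrichmentMatrix:
    def _stats(self, rng, n, G):
        return SampleStatMatrix(
            [f"s{i}" for i in range(n)], [f"g{i}" for i in range(G)],
            rng.normal(size=(n, G)),
        )

    def test_single_cell_equals_scalar_op(self, rng):
        stats = self._stats(rng, 2, 8)
        sets = GeneSetCollection({"A": ["g1", "g4"]})
        mat = enrichment_matrix(stats, sets)
        members = np.isin(stats.gene_ids, ["g1", "g4"])
        for i in range(2):
            assert mat.scores[i, 0] == pytest.approx(
                sample_enrichment_score(stats.stats[i], members)
            )

    def test_gene_order_permutation_invariant(self, rng):
        stats = self._stats(rng, 3, 10)
        sets = GeneSetCollection({"A": ["g0", "g3", "g7"], "B": ["g5", "g6"]})
        perm = rng.permutation(10)
        shuffled = SampleStatMatrix(
            list(stats.sample_ids), [stats.gene_ids[i] for i in perm],
            stats.stats[:, perm],
        )
        np.testing.assert_allclose(
            enrichment_matrix(stats, sets).scores,
            enrichment_matrix(shuffled, sets).scores,
            atol=1e-12,
        )

    def test_random_instance_matches_looped_oracle(self, rng):
        stats = self._stats(rng, 20, 18)
        sets = GeneSetCollection(
            {
                f"S{k}": [f"g{i}" for i in
                          rng.choice(18, size=int(rng.integers(1, 10)),
                                     replace=False)]
                for k in range(10)
            }
        )
        mat = enrichment_matrix(stats, sets)
        for k, name in enumerate(sets.set_names):
            members = np.isin(stats.gene_ids, sets[name])
            for i in range(20):
                assert mat.scores[i, k] == pytest.approx(
                    ks_oracle(list(stats.stats[i]), list(members)), abs=1e-12
                ), (i, name)

    def test_set_with_no_mapped_gene_rejected(self, rng):
        stats = self._stats(rng, 2, 5)
        sets = GeneSetCollection({"bad": ["nope"]})
        with pytest.raises(ValueError, match="bad"):
            enrichment_matrix(stats, sets)


class TestNormalization:
    def _setup(self, rng, n=6, G=12):
        stats = SampleStatMatrix(
            [f"s{i}" for i in range(n)], [f"g{i}" for i in range(G)],
            rng.normal(size=(n, G)),
        )
        sets = GeneSetCollection({"A": ["g0", "g1", "g2"], "B": ["g5", "g8"]})
        labels = PhenotypeLabels(
            list(stats.sample_ids), np.repeat([0, 1], n // 2)
        )
        return stats, sets, labels

    def test_self_background_normalizes_to_unit_magnitude(self, rng):
        stats, sets, labels = self._setup(rng)
        original = enrichment_matrix(stats, sets)
        out = normalize_enrichment(
            original, lambda lab: stats, sets, labels, n_perm=5, seed=0
        )
        nz = original.scores != 0
        np.testing.assert_allclose(np.abs(out.scores[nz]), 1.0, atol=1e-12)

    def test_direct_division_by_background_mean(self):
        # positive scores divide by the mean positive background score
        from pathtask.types import EnrichmentMatrix

        scores = EnrichmentMatrix(["s1", "s2", "s3", "s4"], ["A"],
                                  np.array([[0.6], [0.6], [0.6], [0.6]]))
        labels = PhenotypeLabels(["s1", "s2", "s3", "s4"],
                                 np.array([0, 0, 1, 1]))

        def builder(lab):
            return SampleStatMatrix(
                ["s1", "s2", "s3", "s4"], ["g0", "g1", "g2"],
                np.array([[3.0, 1.0, 2.0]] * 4),
            )

        sets = GeneSetCollection({"A": ["g0"]})
        # background ES for this construction: g0 ranks first -> ES = 0.75...
        bg = enrichment_matrix(builder(None), sets).scores[0, 0]
        out = normalize_enrichment(scores, builder, sets, labels, n_perm=3, seed=1)
        assert out.normalized
        np.testing.assert_allclose(out.scores, 0.6 / bg)

    def test_pooled_background_shares_divisor_across_samples(self, rng):
        stats, sets, labels = self._setup(rng)
        original = enrichment_matrix(stats, sets)
        pooled = normalize_enrichment(
            original, lambda lab: stats, sets, labels, n_perm=4, seed=0,
            pool_samples=True,
        )
        # one divisor per (set, sign): ratios agree for same-signed cells
        for k in range(original.scores.shape[1]):
            for sign in (1, -1):
                cells = np.sign(original.scores[:, k]) == sign
                if cells.sum() < 2:
                    continue
                ratios = pooled.scores[cells, k] / original.scores[cells, k]
                np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_signs_preserved(self, rng):
        stats, sets, labels = self._setup(rng)
        original = enrichment_matrix(stats, sets)

        def builder(lab):
            return SampleStatMatrix(
                list(stats.sample_ids), list(stats.gene_ids),
                np.random.default_rng(abs(hash(tuple(lab.y))) % 2**31)
                .normal(size=stats.stats.shape),
            )

        out = normalize_enrichment(original, builder, sets, labels,
                                   n_perm=20, seed=2)
        assert np.all(np.sign(out.scores) == np.sign(original.scores))
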