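"""Dirichlet posterior-predictive likelihoods and population assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

import timbertrace as tt

from conftest import make_table


class TestGenotypeLikelihood:
    def test_heterozygote_closed_form(self):
        # counts A:3, B:1 (n=4), k=2 -> 2 * 3.5 * 1.5 / (5*6)
        got = tt.rm_genotype_likelihood({1: 3, 2: 1}, (1, 2), k=2)
        assert got == pytest.approx(0.35)

    def test_empty_reference_prior_only(self):
        got = tt.rm_genotype_likelihood({}, (1, 1), k=2)
        assert got == pytest.approx(0.375)

    @pytest.mark.parametrize("k,counts", [(2, {1: 3, 2: 1}), (4, {1: 5, 2: 2, 3: 1, 4: 0}), (3, {})])
    def test_normalizes_over_all_genotypes(self, k, counts):
        alleles = list(range(1, k + 1))
        total = sum(
            tt.rm_genotype_likelihood(counts, (a, b), k=k)
            for a, b in itertools.combinations_with_replacement(alleles, 2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_polya_urn_enumeration_oracle(self):
        # the predictive must equal the expectation of an HWE genotype drawn
        # from Dirichlet(alpha + counts): E[q_i q_j] terms via the Polya urn
        counts = {1: 2, 2: 1}
        k, n = 2, 3
        tau = 1.0 / k
        alpha = {a: counts.get(a, 0) + tau for a in (1, 2)}
        s = n + 2 * tau
        # unordered draw of two alleles without replacement from the urn
        e_hom = alpha[1] * (alpha[1] + 1) / (s * (s + 1))
        e_het = 2 * alpha[1] * alpha[2] / (s * (s + 1))
        assert tt.rm_genotype_likelihood(counts, (1, 1), k) == pytest.approx(e_hom)
        assert tt.rm_genotype_likelihood(counts, (1, 2), k) == pytest.approx(e_het)

    def test_unseen_allele_finite_positive(self):
        got = tt.rm_genotype_likelihood({1: 10}, (1, 7), k=3)
        assert 0 < got < 1

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            tt.rm_genotype_likelihood({1: 1}, (1, 1), k=0)


def fixed_pop_table(two_pop_table, n=20):
    rows = [(f"w{k}", 1, [100, 100, 200, 200]) for k in range(n)]
    rows += [(f"e{k}", 2, [102, 102, 204, 204]) for k in range(n)]
    return make_table(["L1", "L2"], rows, two_pop_table)


class TestSelfAssign:
    def test_fixed_populations_fully_correct(self, two_pop_table):
        table = fixed_pop_table(two_pop_table)
        results, pop_rates, region_rates = tt.self_assign(table)
        assert all(r.correct for r in results)
        assert set(pop_rates["correct_rate"]) == {100.0}
        assert region_rates == {"Western": 100.0, "Eastern": 100.0}

    def test_scores_sum_to_100_and_best_is_argmax(self, two_pop_table):
        table = fixed_pop_table(two_pop_table)
        results, _, _ = tt.self_assign(table)
        for r in results:
            assert sum(r.scores.values()) == pytest.approx(100.0, abs=1e-6)
            assert r.best_population == max(r.log_likelihoods, key=r.log_likelihoods.get)

    def test_twin_populations_split_but_region_holds(self):
        # one gene pool under two labels within one region, plus a distinct
        # population in the other region
        frame = pd.DataFrame(
            dict(code=[1, 2, 3], name=["twinA", "twinB", "east"],
                 region=["Western", "Western", "Eastern"])
        )
        pops = tt.PopulationTable(frame)
        rng = np.random.default_rng(4)
        rows = []
        for k in range(120):
            pop = 1 if k < 60 else 2
            g = [int(a) for a in rng.integers(1, 6, size=8)]
            rows.append((f"t{k}", pop, g))
        for k in range(60):
            g = [int(a) for a in rng.integers(20, 23, size=8)]
            rows.append((f"e{k}", 3, g))
        table = make_table(["L1", "L2", "L3", "L4"], rows, pops)
        results, pop_rates, region_rates = tt.self_assign(table)
        twins = pop_rates[pop_rates.population.isin([1, 2])]
        assert twins["correct_rate"].mean() == pytest.approx(50.0, abs=15.0)
        assert region_rates["Western"] > 95.0

    def test_leave_one_out_removes_optimism(self, default_sim):
        table, _ = default_sim
        sub = table.subset(np.isin(table.population, [1, 2, 4, 25, 26]))
        _, loo_rates, _ = tt.self_assign(sub, leave_one_out=True)
        _, resub_rates, _ = tt.self_assign(sub, leave_one_out=False)
        assert resub_rates["correct_rate"].mean() >= loo_rates["correct_rate"].mean()

    def test_small_populations_excluded(self, default_sim):
        table, _ = default_sim
        _, pop_rates, _ = tt.self_assign(table, min_pop_size=16)
        assert set(pop_rates["population"]).isdisjoint({3, 14, 22})
        assert len(pop_rates) == 24

    def test_result_invariant_to_individual_order(self, two_pop_table):
        table = fixed_pop_table(two_pop_table, n=10)
        rng = np.random.default_rng(1)
        shuffled = table.subset(rng.permutation(table.n_individuals))
        r1 = {r.individual_id: r.best_population for r in tt.self_assign(table, min_pop_size=10)[0]}
        r2 = {r.individual_id: r.best_population for r in tt.self_assign(shuffled, min_pop_size=10)[0]}
        assert r1 == r2


class TestAssignQuery:
    def test_threshold_101_unassigns_everything(self, two_pop_table):
        table = fixed_pop_table(two_pop_table)
        results = tt.assign_query(table, table, score_threshold=101.0)
        assert all(r.assigned is None for r in results)
        assert all(r.status == "unassigned (below threshold)" for r in results)

    def test_locus_mismatch_rejected(self, two_pop_table):
        table = fixed_pop_table(two_pop_table)
        queries = make_table(["LX"], [("q1", 1, [100, 100])], two_pop_table)
        with pytest.raises(ValueError, match="LX"):
            tt.assign_query(table, queries)

    def test_all_missing_query_rejected(self, two_pop_table):
        table = fixed_pop_table(two_pop_table)
        queries = make_table(["L1", "L2"], [("q1", 1, [0, 0, 0, 0])], two_pop_table)
        with pytest.raises(ValueError, match="all loci missing"):
            tt.assign_query(table, queries)

    def test_queries_from_source_population_rank_it_top(self, default_sim):
        table, truth = default_sim
        # draw fresh genotypes from population 16's latent frequencies
        rng = np.random.default_rng(17)
        labels = [np.array(l) for l in truth["allele_labels"]]
        freqs = [np.array(p) for p in truth["population_freqs"][16]]
        n = 30
        calls = np.zeros((n, 15, 2), dtype=np.int64)
        for j in range(15):
            calls[:, j, 0] = labels[j][rng.choice(len(freqs[j]), size=n, p=freqs[j])]
            calls[:, j, 1] = labels[j][rng.choice(len(freqs[j]), size=n, p=freqs[j])]
        queries = tt.STRGenotypeTable(
            [f"q{i}" for i in range(n)], table.loci, calls,
            np.full(n, 16, dtype=np.int64), table.populations,
        )
        results = tt.assign_query(table, queries, score_threshold=0.0)
        top_correct = np.mean([r.best_population == 16 for r in results])
        _, pop_rates, _ = tt.self_assign(table)
        self_rate = float(pop_rates.loc[pop_rates.population == 16, "correct_rate"].iloc[0]) / 100
        assert top_correct >= self_rate - 0.2
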