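"""Allele frequencies, forensic parameters, exact tests, multiple testing."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

import timbertrace as tt

from conftest import make_table


def biallelic_table(genotypes, two_pop_table, locus="LocA"):
    rows = [
        (f"i{k}", 1, [a, b]) for k, (a, b) in enumerate(genotypes)
    ]
    return make_table([locus], rows, two_pop_table)


class TestAlleleFrequencies:
    def test_direct_counts(self, two_pop_table):
        table = biallelic_table([(1, 1), (1, 1), (1, 2), (2, 2)], two_pop_table)
        db = tt.allele_frequencies(table, apply_floor=False)
        assert db.frequencies["LocA"] == {1: pytest.approx(0.625), 2: pytest.approx(0.375)}

    @pytest.mark.parametrize("n, expected", [(1032, 0.0024), (100, 0.0250)])
    def test_floor_value(self, n, expected, two_pop_table):
        table = biallelic_table([(1, 2)] * n, two_pop_table)
        db = tt.allele_frequencies(table)
        assert round(db.floor, 4) == expected

    def test_flooring_raises_only_subfloor_alleles(self, two_pop_table):
        # 100 individuals: one allele seen once (freq 0.005 < floor 0.025)
        genotypes = [(1, 1)] * 99 + [(1, 2)]
        table = biallelic_table(genotypes, two_pop_table)
        raw = tt.allele_frequencies(table, apply_floor=False)
        floored = tt.allele_frequencies(table)
        assert floored.frequencies["LocA"][2] == pytest.approx(floored.floor)
        assert floored.frequencies["LocA"][1] == raw.frequencies["LocA"][1]
        for a in raw.frequencies["LocA"]:
            assert floored.frequencies["LocA"][a] >= raw.frequencies["LocA"][a]

    def test_unseen_allele_lookup_returns_floor(self, two_pop_table):
        table = biallelic_table([(1, 1), (1, 2)], two_pop_table)
        db = tt.allele_frequencies(table)
        assert db.freq("LocA", 999) == db.floor

    def test_empty_pool_rejected(self, two_pop_table):
        table = biallelic_table([(1, 2)], two_pop_table)
        with pytest.raises(ValueError, match="empty pool"):
            tt.allele_frequencies(table, pool="Eastern")


class TestLocusSummary:
    def test_two_equifrequent_alleles_closed_forms(self, two_pop_table):
        # large-n limit of PIC and He for p = q = 0.5
        n = 5000
        genotypes = [(1, 1)] * (n // 4) + [(2, 2)] * (n // 4) + [(1, 2)] * (n // 2)
        table = biallelic_table(genotypes, two_pop_table)
        (s,) = tt.locus_summary(table)
        assert s.A == 2
        assert s.PIC == pytest.approx(0.375, abs=1e-12)
        assert s.He == pytest.approx(0.5, abs=1e-3)

    def test_matching_probability_from_genotype_proportions(self, two_pop_table):
        table = biallelic_table([(1, 1), (1, 1), (1, 2), (1, 2)], two_pop_table)
        (s,) = tt.locus_summary(table)
        assert s.MP == pytest.approx(0.5)
        assert s.PD == pytest.approx(0.5)

    def test_monomorphic_locus_degenerate_values(self, two_pop_table):
        table = biallelic_table([(1, 1)] * 4, two_pop_table)
        (s,) = tt.locus_summary(table)
        assert (s.A, s.Ho, s.He, s.PIC, s.MP, s.PD) == (1, 0.0, 0.0, 0.0, 1.0, 0.0)

    def test_panel_invariants_on_simulated_data(self, default_sim):
        table, _ = default_sim
        for s in tt.locus_summary(table):
            assert s.MP + s.PD == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= s.PIC <= s.He <= 1.0
            assert 0.0 <= s.Ho <= 1.0


def exact_hwe_pvalue_two_alleles(n_het_obs, nA, nB):
    """Full-enumeration exact HWE p-value for a biallelic locus.

    The heterozygote count h determines the genotype array; its conditional
    probability given allele counts (nA, nB) is
    n! / (n_AA! h! n_BB!) * 2^h * nA! nB! / (2n)!.
    """
    n = (nA + nB) // 2
    probs = {}
    for h in range(n + 1):
        if (nA - h) < 0 or (nB - h) < 0 or (nA - h) % 2 or (nB - h) % 2:
            continue
        naa, nbb = (nA - h) // 2, (nB - h) // 2
        logp = (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(h + 1) - gammaln(nbb + 1)
            + h * math.log(2)
            + gammaln(nA + 1) + gammaln(nB + 1) - gammaln(2 * n + 1)
        )
        probs[h] = math.exp(logp)
    assert sum(probs.values()) == pytest.approx(1.0)
    p_obs = probs[n_het_obs]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


class TestHWEExact:
    def test_complete_heterozygote_deficit_rejected(self, two_pop_table):
        table = biallelic_table([(1, 1)] * 5 + [(2, 2)] * 5, two_pop_table)
        p = tt.hwe_exact_test(table, None, "LocA", reps=2000, seed=1)
        exact = exact_hwe_pvalue_two_alleles(0, 10, 10)
        assert p < 0.05
        assert p == pytest.approx(exact, abs=0.02)

    def test_equilibrium_sample_not_rejected(self, two_pop_table):
        table = biallelic_table(
            [(1, 1)] * 9 + [(1, 2)] * 12 + [(2, 2)] * 4, two_pop_table
        )
        p = tt.hwe_exact_test(table, None, "LocA", reps=2000, seed=1)
        exact = exact_hwe_pvalue_two_alleles(12, 30, 20)
        assert p == pytest.approx(exact, abs=0.05)
        assert p > 0.2

    def test_monomorphic_returns_one(self, two_pop_table):
        table = biallelic_table([(1, 1)] * 6, two_pop_table)
        assert tt.hwe_exact_test(table, None, "LocA", reps=1000, seed=0) == 1.0

    def test_seed_reproducibility_and_reps_convergence(self, two_pop_table):
        table = biallelic_table([(1, 1)] * 8 + [(1, 2)] * 4 + [(2, 2)] * 8, two_pop_table)
        p1 = tt.hwe_exact_test(table, None, "LocA", reps=2000, seed=5)
        p2 = tt.hwe_exact_test(table, None, "LocA", reps=2000, seed=5)
        assert p1 == p2
        p_small = tt.hwe_exact_test(table, None, "LocA", reps=1000, seed=5)
        p_big = tt.hwe_exact_test(table, None, "LocA", reps=10000, seed=5)
        assert abs(p_small - p_big) < 0.02


class TestLEExact:
    def test_identical_columns_strongly_linked(self, two_pop_table):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(20):
            g = sorted(rng.integers(1, 5, size=2))
            rows.append((f"i{k}", 1, [g[0], g[1], g[0], g[1]]))
        table = make_table(["LocA", "LocB"], rows, two_pop_table)
        p = tt.le_exact_test(table, None, ("LocA", "LocB"), reps=2000, seed=1)
        assert p < 0.01

    def test_monomorphic_partner_returns_one(self, two_pop_table):
        rows = [(f"i{k}", 1, [1, 1, 10, 10 + (k % 2)]) for k in range(10)]
        table = make_table(["LocA", "LocB"], rows, two_pop_table)
        assert tt.le_exact_test(table, None, ("LocA", "LocB"), reps=1000, seed=0) == 1.0

    def test_fifteen_locus_panel_emits_105_pairs(self, default_sim):
        table, _ = default_sim
        small = table.subset(np.arange(40))
        frame = tt.le_all_pairs(small, reps=1000, seed=2)
        assert len(frame) == 105
        assert frame[["locus_a", "locus_b"]].drop_duplicates().shape[0] == 105


class TestMultipleTesting:
    def test_bonferroni_threshold_for_panel(self):
        assert round(tt.bonferroni_threshold(0.05, 15), 4) == 0.0033

    def test_all_ones_never_rejected(self):
        assert not tt.multiple_testing([1.0] * 8, method="bonferroni").any()
        assert not tt.multiple_testing([1.0] * 8, method="sequential").any()

    def test_holm_sequential_hand_worked(self):
        # thresholds 0.05/3, 0.05/2, 0.05/1 applied in ascending order
        rejected = tt.multiple_testing([0.001, 0.02, 0.5], method="sequential")
        assert rejected.tolist() == [True, True, False]
        # bonferroni is stricter on the middle p-value
        bonf = tt.multiple_testing([0.001, 0.02, 0.5], method="bonferroni")
        assert bonf.tolist() == [True, False, False]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tt.multiple_testing([])
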