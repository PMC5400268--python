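"""STR database characterization.

Allele frequencies with the 5/(2N) minimum-frequency floor, per-locus
diversity and forensic parameters (allele count A, observed and unbiased
expected heterozygosity, PIC, matching probability MP and power of
discrimination PD = 1 - MP), Monte-Carlo exact tests for Hardy-Weinberg
equilibrium and pairwise genotypic linkage equilibrium, and
multiple-testing corrections (Bonferroni and sequential/Holm).

Frequencies and Ho use per-locus complete cases; the frequency floor uses
the pool's individual count N so every recorded allele is effectively
observed at least five times.  Flooring does not renormalize the remaining
frequencies (a conservative convention); renormalization is available
behind a flag.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_io import MISSING, STRGenotypeTable, _pool_mask

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyDatabase:
    """Per-locus allele frequency vectors for a reference pool.

    ``frequencies[locus][allele]`` is the (possibly floored) frequency.
    ``floor`` = 5/(2N) with N the number of individuals in the pool.
    Lookups of alleles absent from the database return the floor when the
    database is floored (a query allele unseen in the reference still gets
    positive, conservative mass).
    """

    frequencies: dict[str, dict[int, float]]
    n_individuals: int
    floor: float
    pool_label: str
    floored: bool = True
    raw: dict[str, dict[int, float]] = field(default_factory=dict, repr=False)

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def freq(self, locus: str, allele: int) -> float:
        try:
            table = self.frequencies[locus]
        except KeyError:
            raise KeyError(f"unknown locus {locus!r}") from None
        f = table.get(int(allele))
        if f is None:
            if self.floored:
                return self.floor
            raise KeyError(f"allele {allele} not recorded at {locus} in unfloored database")
        return f

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(locus=loc, allele=a, frequency=f)
            for loc, table in self.frequencies.items()
            for a, f in sorted(table.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class LocusSummary:
    """Diversity and forensic parameters for one locus."""

    locus: str
    n: int          # complete-case individuals
    A: int          # distinct alleles
    Ho: float       # observed heterozygosity
    He: float       # unbiased expected heterozygosity
    PIC: float      # polymorphic information content
    MP: float       # matching probability (sum of squared genotype proportions)
    PD: float       # power of discrimination = 1 - MP
    hwe_p: float | None = None


def _locus_calls(table: STRGenotypeTable, mask: np.ndarray, locus_idx: int) -> np.ndarray:
    """Complete-case diploid calls (k, 2) at one locus within a pool."""
    calls = table.calls[mask, locus_idx, :]
    ok = (calls > MISSING).all(axis=1)
    return calls[ok]


def allele_frequencies(
    table: STRGenotypeTable,
    pool=None,
    apply_floor: bool = True,
    renormalize: bool = False,
    pool_label: str | None = None,
) -> AlleleFrequencyDatabase:
    """Observed allele frequencies per locus for a pool of individuals.

    The floor 5/(2N) is applied by raising sub-floor frequencies without
    renormalizing the rest unless ``renormalize`` is set.
    """
    mask = _pool_mask(table, pool)
    n_pool = int(mask.sum())
    if n_pool == 0:
        raise ValueError("empty pool")
    floor = 5.0 / (2.0 * n_pool)
    raw: dict[str, dict[int, float]] = {}
    floored: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, mask, j)
        if calls.size == 0:
            raise ValueError(f"no complete calls at locus {locus} in pool")
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        freqs = counts / counts.sum()
        raw[locus] = {int(a): float(f) for a, f in zip(alleles, freqs)}
        if apply_floor:
            vals = np.maximum(freqs, floor)
            if renormalize:
                vals = vals / vals.sum()
            floored[locus] = {int(a): float(f) for a, f in zip(alleles, vals)}
    label = pool_label if pool_label is not None else ("all" if pool is None else str(pool))
    if apply_floor:
        return AlleleFrequencyDatabase(floored, n_pool, floor, label, floored=True, raw=raw)
    return AlleleFrequencyDatabase(raw, n_pool, floor, label, floored=False, raw=raw)


# ---------------------------------------------------------------------------
# Locus summary statistics
# ---------------------------------------------------------------------------


def locus_summary(
    table: STRGenotypeTable,
    pool=None,
    hwe_reps: int | None = None,
    seed: int | None = None,
) -> list[LocusSummary]:
    """Table of per-locus diversity and forensic parameters.

    He is Nei's unbiased estimate (2n/(2n-1))(1 - sum p_i^2); PIC is
    1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2; MP is the sum of squared
    observed genotype proportions.  When ``hwe_reps`` is given, a seeded
    Monte-Carlo exact HWE test is run per locus.
    """
    mask = _pool_mask(table, pool)
    rng = np.random.default_rng(seed)
    out: list[LocusSummary] = []
    for j, locus in enumerate(table.loci):
        calls = _locus_calls(table, mask, j)
        n = calls.shape[0]
        if n < 2:
            raise ValueError(f"fewer than 2 complete genotypes at {locus}")
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / counts.sum()
        A = len(alleles)
        het = calls[:, 0] != calls[:, 1]
        Ho = float(het.mean())
        if A == 1:
            out.append(LocusSummary(locus, n, 1, 0.0, 0.0, 0.0, 1.0, 0.0, hwe_p=1.0 if hwe_reps else None))
            continue
        sum_p2 = float(np.sum(p**2))
        He = (2 * n / (2 * n - 1)) * (1 - sum_p2)
        PIC = 1 - sum_p2 - (float(np.sum(p**2) ** 2) - float(np.sum(p**4)))
        # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
        geno = np.sort(calls, axis=1)
        codes = geno[:, 0] * (alleles.max() + 1) + geno[:, 1]
        _, gcounts = np.unique(codes, return_counts=True)
        gprop = gcounts / n
        MP = float(np.sum(gprop**2))
        PD = 1.0 - MP
        hwe_p = None
        if hwe_reps:
            hwe_p = hwe_exact_test(table, pool, locus, reps=hwe_reps, rng=rng)
        out.append(LocusSummary(locus, n, A, Ho, float(He), float(PIC), MP, PD, hwe_p))
    return out


def locus_summary_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


# ---------------------------------------------------------------------------
# Exact tests (Monte-Carlo)
# ---------------------------------------------------------------------------


def _genotype_array_logprob(pair_codes: np.ndarray, n_het: int, n: int) -> float:
    """Log conditional probability of a genotype array given allele counts.

    log P = log n! + h log 2 + sum_a log(n_a!) - log (2n)! - sum_g log(n_g!)
    where only the genotype-count term and the heterozygote count vary under
    permutations of the allele vector; the constant terms cancel in the
    comparison, so they are omitted.
    """
    _, gcounts = np.unique(pair_codes, return_counts=True)
    return n_het * math.log(2.0) - float(gammaln(gcounts + 1.0).sum())


def hwe_exact_test(
    table: STRGenotypeTable,
    pool,
    locus: str,
    reps: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium at one locus.

    The 2n observed alleles are randomly re-paired into diploid genotypes;
    the statistic is the conditional probability of the genotype array given
    the allele counts, and the p-value is the proportion of permuted arrays
    at most as probable as the observed one, with the +1 correction in
    numerator and denominator.  Monomorphic loci return p = 1.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable exact-test p-value")
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = _pool_mask(table, pool)
    calls = _locus_calls(table, mask, table.locus_index(locus))
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"no complete genotypes at {locus}")
    alleles = calls.ravel()
    uniq = np.unique(alleles)
    if len(uniq) < 2:
        return 1.0
    K = int(uniq.max()) + 1

    geno = np.sort(calls, axis=1)
    obs_codes = geno[:, 0] * K + geno[:, 1]
    obs_lp = _genotype_array_logprob(obs_codes, int((calls[:, 0] != calls[:, 1]).sum()), n)

    # one vectorized shuffle of all replicates, then per-replicate counting
    perms = np.tile(alleles, (reps, 1))
    perms = rng.permuted(perms, axis=1).reshape(reps, n, 2)
    lo = np.minimum(perms[:, :, 0], perms[:, :, 1])
    hi = np.maximum(perms[:, :, 0], perms[:, :, 1])
    codes = lo * K + hi
    n_het = (lo != hi).sum(axis=1)
    hits = 0
    tol = 1e-9
    for r in range(reps):
        lp = _genotype_array_logprob(codes[r], int(n_het[r]), n)
        if lp <= obs_lp + tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def le_exact_test(
    table: STRGenotypeTable,
    pool,
    locus_pair: tuple[str, str],
    reps: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation exact test of genotypic linkage equilibrium for two loci.

    One locus's genotypes are shuffled among individuals; the statistic is
    the log-likelihood-ratio (G) of the two-locus genotype contingency
    table.  Either locus monomorphic returns p = 1.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable exact-test p-value")
    if rng is None:
        rng = np.random.default_rng(seed)
    la, lb = locus_pair
    mask = _pool_mask(table, pool)
    ja, jb = table.locus_index(la), table.locus_index(lb)
    calls = table.calls[mask][:, [ja, jb], :]
    ok = (calls > MISSING).all(axis=(1, 2))
    calls = calls[ok]
    n = calls.shape[0]
    if n == 0:
        raise ValueError(f"no complete genotypes at pair ({la}, {lb})")

    def geno_codes(c: np.ndarray) -> np.ndarray:
        g = np.sort(c, axis=1)
        _, inv = np.unique(g[:, 0] * (g.max() + 1) + g[:, 1], return_inverse=True)
        return inv

    ca = geno_codes(calls[:, 0, :])
    cb = geno_codes(calls[:, 1, :])
    Ka, Kb = ca.max() + 1, cb.max() + 1
    if Ka < 2 or Kb < 2:
        return 1.0

    def g_stat(a_codes: np.ndarray, b_codes: np.ndarray) -> float:
        joint = np.bincount(a_codes * Kb + b_codes, minlength=Ka * Kb).reshape(Ka, Kb)
        row = joint.sum(axis=1, keepdims=True)
        col = joint.sum(axis=0, keepdims=True)
        expected = row * col / n
        nz = joint > 0
        return 2.0 * float((joint[nz] * np.log(joint[nz] / expected[nz])).sum())

    obs = g_stat(ca, cb)
    perm_b = np.tile(cb, (reps, 1))
    perm_b = rng.permuted(perm_b, axis=1)
    hits = 0
    tol = 1e-9
    for r in range(reps):
        if g_stat(ca, perm_b[r]) >= obs - tol:
            hits += 1
    return (hits + 1) / (reps + 1)


def le_all_pairs(
    table: STRGenotypeTable,
    pool=None,
    reps: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All C(L,2) pairwise linkage-equilibrium tests for the panel."""
    rng = np.random.default_rng(seed)
    rows = []
    for la, lb in itertools.combinations(table.loci, 2):
        p = le_exact_test(table, pool, (la, lb), reps=reps, rng=rng)
        rows.append(dict(locus_a=la, locus_b=lb, p_value=p))
    logger.info("ran %d pairwise LE tests", len(rows))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def multiple_testing(
    pvals, alpha: float = 0.05, method: str = "bonferroni"
) -> np.ndarray:
    """Reject/keep decisions for a family of p-values.

    ``bonferroni``: reject iff p < alpha/m.  ``sequential`` (Holm): sort
    ascending and reject while p_(i) < alpha/(m - i + 1), stopping at the
    first failure.  Returns a boolean array in the original order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return p < alpha / m
    if method == "sequential":
        order = np.argsort(p, kind="stable")
        reject = np.zeros(m, dtype=bool)
        for i, idx in enumerate(order):
            if p[idx] < alpha / (m - i):
                reject[idx] = True
            else:
                break
        return reject
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m <= 0:
        raise ValueError("m must be positive")
    return alpha / m
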