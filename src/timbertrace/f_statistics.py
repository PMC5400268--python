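"""Weir-Cockerham F-statistics with a locus bootstrap.

Coancestry theta (F_ST) and within-population inbreeding f (F_IS) are
estimated from the 1984 Weir & Cockerham variance components: for each
locus and allele, an among-population component (a), an
among-individual-within-population component (b) and a within-individual
component (c), computed from per-population allele frequencies, observed
heterozygote frequencies and sample sizes (the n-bar / n_c weights handle
unequal sizes).  Multilocus estimates are ratio-of-sums across alleles and
loci:

    theta = sum(a) / sum(a + b + c)
    f     = 1 - sum(c) / sum(b + c)

Confidence intervals are percentile bootstrap over loci (resampling loci
with replacement), the convention used when an STR panel is the sampling
unit.  Hierarchical levels (e.g. the national pool vs. each region) are
obtained by selecting population subsets; populations are always the
grouping unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, STRGenotypeTable, _pool_mask

logger = logging.getLogger(__name__)


@dataclass
class FStatResult:
    level: str
    theta: float | None
    f: float
    ci_theta: tuple[float, float] | None = None
    ci_f: tuple[float, float] | None = None
    reps: int = 0

    def theta_significant(self) -> bool | None:
        """True when the bootstrap CI for theta excludes zero."""
        if self.ci_theta is None:
            return None
        lo, hi = self.ci_theta
        return lo > 0 or hi < 0


@dataclass
class LocusComponents:
    """Per-allele Weir-Cockerham variance components at one locus."""

    locus: str
    alleles: np.ndarray
    a: np.ndarray  # among populations (None-like NaN when only one population)
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals

    def sums(self) -> tuple[float, float, float]:
        a = 0.0 if np.isnan(self.a).all() else float(np.nansum(self.a))
        return a, float(self.b.sum()), float(self.c.sum())


def _per_population_arrays(
    table: STRGenotypeTable, mask: np.ndarray, locus_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pops kept, n_i, p_i matrix, h_i matrix) at a locus, complete-case."""
    calls = table.calls[mask, locus_idx, :]
    pops = table.population[mask]
    ok = (calls > MISSING).all(axis=1)
    calls, pops = calls[ok], pops[ok]
    if calls.size == 0:
        raise ValueError("no complete genotypes at locus")
    alleles = np.unique(calls.ravel())
    K = len(alleles)
    coded = np.searchsorted(alleles, calls)  # (n, 2) allele indices
    pop_ids = np.unique(pops)
    n_i = np.zeros(len(pop_ids))
    p = np.zeros((len(pop_ids), K))
    h = np.zeros((len(pop_ids), K))
    for i, pid in enumerate(pop_ids):
        sel = pops == pid
        sub = coded[sel]
        n = sub.shape[0]
        n_i[i] = n
        if n == 0:
            continue
        p[i] = np.bincount(sub.ravel(), minlength=K) / (2 * n)
        het = sub[:, 0] != sub[:, 1]
        if het.any():
            # heterozygote frequency per allele: one copy from each slot
            h[i] = (
                np.bincount(sub[het, 0], minlength=K)
                + np.bincount(sub[het, 1], minlength=K)
            ) / n
    keep = n_i > 0
    return pop_ids[keep], n_i[keep], p[keep], h[keep], alleles


def variance_components(
    table: STRGenotypeTable, pool=None
) -> list[LocusComponents]:
    """Per-locus, per-allele Weir-Cockerham components (a, b, c).

    Populations within the pool are the grouping unit.  With a single
    population the among-population component a is undefined (NaN); b and c
    remain estimable so inbreeding-only estimation is still possible.
    """
    mask = _pool_mask(table, pool)
    out = []
    for j, locus in enumerate(table.loci):
        pop_ids, n_i, p, h, alleles = _per_population_arrays(table, mask, j)
        r = len(pop_ids)
        nbar = n_i.mean()
        if nbar <= 1:
            raise ValueError(f"{locus}: populations must have >1 genotype for the small-sample terms")
        a_arr = np.full(len(alleles), np.nan)
        b_arr = np.zeros(len(alleles))
        c_arr = np.zeros(len(alleles))
        if r >= 2:
            n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for k in range(len(alleles)):
            pbar = float((n_i * p[:, k]).sum() / (r * nbar))
            hbar = float((n_i * h[:, k]).sum() / (r * nbar))
            if r >= 2:
                s2 = float((n_i * (p[:, k] - pbar) ** 2).sum() / ((r - 1) * nbar))
                a_arr[k] = (nbar / n_c) * (
                    s2
                    - (1.0 / (nbar - 1))
                    * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
                )
                b_arr[k] = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar)
                    - ((r - 1) / r) * s2
                    - ((2 * nbar - 1) / (4 * nbar)) * hbar
                )
            else:
                b_arr[k] = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - ((2 * nbar - 1) / (4 * nbar)) * hbar
                )
            c_arr[k] = hbar / 2.0
        out.append(LocusComponents(locus, alleles, a_arr, b_arr, c_arr))
    return out


def estimate_theta_f(
    table: STRGenotypeTable,
    pool=None,
    level: str | None = None,
    components: list[LocusComponents] | None = None,
) -> FStatResult:
    """Ratio-of-sums theta and f over all loci and alleles in a pool."""
    if components is None:
        components = variance_components(table, pool)
    sa = sb = sc = 0.0
    any_a = False
    for comp in components:
        a, b, c = comp.sums()
        if not np.isnan(comp.a).all():
            any_a = True
        sa += a
        sb += b
        sc += c
    if sb + sc == 0 and sa == 0:
        raise ValueError("all loci monomorphic; F-statistics undefined")
    if not any_a:
        raise ValueError("theta undefined with a single population (f-only estimation available)")
    theta = sa / (sa + sb + sc)
    # no within-population variation (e.g. fixed populations): f is 0/0
    f = 1.0 - sc / (sb + sc) if (sb + sc) != 0 else float("nan")
    label = level if level is not None else ("all" if pool is None else str(pool))
    return FStatResult(label, float(theta), float(f))


def estimate_f(table: STRGenotypeTable, pool=None, level: str | None = None) -> FStatResult:
    """Within-population inbreeding f only (valid with a single population)."""
    components = variance_components(table, pool)
    sb = sum(c.sums()[1] for c in components)
    sc = sum(c.sums()[2] for c in components)
    if sb + sc == 0:
        raise ValueError("all loci monomorphic; f undefined")
    label = level if level is not None else ("all" if pool is None else str(pool))
    return FStatResult(label, None, float(1.0 - sc / (sb + sc)))


def bootstrap_ci(
    table: STRGenotypeTable,
    pool=None,
    level: str | None = None,
    reps: int = 1000,
    seed: int | None = None,
    force: bool = False,
) -> FStatResult:
    """Percentile bootstrap over loci for theta and f (2.5% / 97.5% bounds).

    Per-locus component sums are computed once; each replicate resamples
    loci with replacement and re-forms the ratio-of-sums estimates.
    """
    if reps < 100 and not force:
        raise ValueError("reps < 100 gives unstable percentile bounds; pass force=True to override")
    components = variance_components(table, pool)
    if len(components) < 2:
        raise ValueError("bootstrap over loci requires >= 2 loci")
    point = estimate_theta_f(table, pool, level=level, components=components)
    sums = np.array([c.sums() for c in components])  # (L, 3)
    L = sums.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(reps, L))
    picked = sums[idx]  # (reps, L, 3)
    sa = picked[:, :, 0].sum(axis=1)
    sb = picked[:, :, 1].sum(axis=1)
    sc = picked[:, :, 2].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = sa / (sa + sb + sc)
        fs = 1.0 - sc / (sb + sc)
    thetas = thetas[np.isfinite(thetas)]
    fs = fs[np.isfinite(fs)]
    ci_theta = (float(np.percentile(thetas, 2.5)), float(np.percentile(thetas, 97.5)))
    ci_f = (float(np.percentile(fs, 2.5)), float(np.percentile(fs, 97.5)))
    return FStatResult(point.level, point.theta, point.f, ci_theta, ci_f, reps)
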