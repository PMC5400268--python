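"""Bayesian multilocus population assignment.

Candidate populations are scored with Dirichlet posterior-predictive
genotype likelihoods (the Rannala-Mountain construction): with n_i copies
of allele i observed in a candidate's reference sample of n allele copies
at a locus, and k distinct alleles observed at that locus across the whole
reference, the predictive probability of an unordered diploid genotype is

    heterozygote (i != j): 2 (n_i + 1/k)(n_j + 1/k) / [(n+1)(n+2)]
    homozygote:            (n_i + 1/k)(n_i + 1 + 1/k) / [(n+1)(n+2)]

The 1/k prior mass keeps likelihoods finite for alleles never seen in a
reference sample.  Multilocus log-likelihoods sum over loci (missing loci
are skipped symmetrically across candidates); scores are likelihoods
normalized to percentages over the candidate set.

Self-assignment removes each individual's own two alleles per locus from
its population's counts (leave-one-out) before scoring, so the reported
correct-assignment rates are not trivially optimistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, REGIONS, STRGenotypeTable

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned (below threshold)"


@dataclass
class AssignmentResult:
    individual_id: str
    log_likelihoods: dict[int, float]
    scores: dict[int, float]           # percentages summing to 100
    best_population: int
    best_region: str
    true_population: int | None = None
    correct: bool | None = None
    assigned: int | None = None        # query mode: None when below threshold
    status: str = "assigned"


def rm_genotype_likelihood(
    ref_allele_counts: Mapping[int, float] | Sequence[float],
    genotype: tuple[int, int],
    k: int,
) -> float:
    """Posterior-predictive probability of one diploid genotype.

    ``ref_allele_counts`` maps allele label -> count in the candidate
    reference (alleles absent from the mapping count 0); ``k`` is the
    number of distinct alleles observed at the locus across all candidate
    populations, setting the Dirichlet(1/k, ..., 1/k) prior.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(ref_allele_counts, Mapping):
        counts = ref_allele_counts
        n = float(sum(counts.values()))
        get = lambda a: float(counts.get(a, 0.0))
    else:
        arr = np.asarray(ref_allele_counts, dtype=float)
        n = float(arr.sum())
        get = lambda a: float(arr[a])
    if n < 0 or any(v < 0 for v in ([get(genotype[0]), get(genotype[1])])):
        raise ValueError("allele counts must be non-negative")
    tau = 1.0 / k
    a, b = genotype
    denom = (n + 1.0) * (n + 2.0)
    if a == b:
        na = get(a)
        return (na + tau) * (na + 1.0 + tau) / denom
    return 2.0 * (get(a) + tau) * (get(b) + tau) / denom


def _reference_arrays(reference: STRGenotypeTable, candidates: list[int]):
    """Per-locus allele codes, per-candidate count matrices and k values."""
    per_locus = []
    pop_index = {p: i for i, p in enumerate(candidates)}
    cand_mask = np.isin(reference.population, candidates)
    for j, locus in enumerate(reference.loci):
        calls = reference.calls[cand_mask, j, :]
        pops = reference.population[cand_mask]
        ok = (calls > MISSING).all(axis=1)
        calls, pops = calls[ok], pops[ok]
        alleles = np.unique(calls.ravel())
        K = len(alleles)
        coded = np.searchsorted(alleles, calls)
        counts = np.zeros((len(candidates), K))
        for p in np.unique(pops):
            sel = pops == p
            counts[pop_index[int(p)]] = np.bincount(coded[sel].ravel(), minlength=K)
        per_locus.append(dict(locus=locus, alleles=alleles, counts=counts, k=K))
    return per_locus


def _score_individual(
    per_locus,
    genotypes: Sequence[tuple[int, int] | None],
    candidates: list[int],
    loo_pop_idx: int | None = None,
) -> np.ndarray:
    """Multilocus log-likelihood vector over candidates for one individual."""
    ll = np.zeros(len(candidates))
    for ref, g in zip(per_locus, genotypes):
        if g is None:
            continue
        a, b = g
        alleles, counts, k = ref["alleles"], ref["counts"], ref["k"]
        tau = 1.0 / k
        ia = np.searchsorted(alleles, a)
        ib = np.searchsorted(alleles, b)
        seen_a = ia < len(alleles) and alleles[ia] == a
        seen_b = ib < len(alleles) and alleles[ib] == b
        na = counts[:, ia].copy() if seen_a else np.zeros(len(counts))
        nb = counts[:, ib].copy() if seen_b else np.zeros(len(counts))
        n = counts.sum(axis=1)
        if loo_pop_idx is not None:
            n[loo_pop_idx] -= 2
            if a == b:
                if seen_a:
                    na[loo_pop_idx] -= 2
                    nb = na
            else:
                if seen_a:
                    na[loo_pop_idx] -= 1
                if seen_b:
                    nb[loo_pop_idx] -= 1
        denom = (n + 1.0) * (n + 2.0)
        if a == b:
            vals = (na + tau) * (na + 1.0 + tau) / denom
        else:
            vals = 2.0 * (na + tau) * (nb + tau) / denom
        ll += np.log(vals)
    return ll


def _scores_from_ll(ll: np.ndarray) -> np.ndarray:
    w = np.exp(ll - ll.max())
    return 100.0 * w / w.sum()


def _genotypes_of(table: STRGenotypeTable, i: int, loci: list[str]):
    out = []
    for locus in loci:
        j = table.locus_index(locus)
        a, b = int(table.calls[i, j, 0]), int(table.calls[i, j, 1])
        out.append(None if a == MISSING or b == MISSING else (a, b))
    return out


def self_assign(
    table: STRGenotypeTable,
    min_pop_size: int = 16,
    leave_one_out: bool = True,
) -> tuple[list[AssignmentResult], pd.DataFrame, dict[str, float]]:
    """Leave-one-out self-assignment of every reference individual.

    Populations below ``min_pop_size`` are excluded from the candidate set
    and from the test set.  Returns the per-individual results, a
    per-population correct-rate table, and per-region correct rates (an
    individual is regionally correct when its best population lies in its
    true region).
    """
    counts = table.pop_counts()
    candidates = sorted(p for p, c in counts.items() if c >= min_pop_size)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate populations after size exclusion")
    if not leave_one_out:
        logger.warning("self-assignment without leave-one-out is upward-biased")
    region_map = table.populations.region_map()
    per_locus = _reference_arrays(table, candidates)
    pop_index = {p: i for i, p in enumerate(candidates)}

    results: list[AssignmentResult] = []
    for i, ind in enumerate(table.individuals):
        true_pop = int(table.population[i])
        if true_pop not in pop_index:
            continue
        genotypes = _genotypes_of(table, i, table.loci)
        if all(g is None for g in genotypes):
            raise ValueError(f"{ind}: all loci missing")
        loo = pop_index[true_pop] if leave_one_out else None
        ll = _score_individual(per_locus, genotypes, candidates, loo_pop_idx=loo)
        best_idx = int(np.argmax(ll))
        if (ll == ll[best_idx]).sum() > 1:
            logger.warning("%s: tied likelihoods; keeping first candidate in order", ind)
        best = candidates[best_idx]
        scores = _scores_from_ll(ll)
        results.append(
            AssignmentResult(
                ind,
                {p: float(v) for p, v in zip(candidates, ll)},
                {p: float(s) for p, s in zip(candidates, scores)},
                best,
                region_map[best],
                true_population=true_pop,
                correct=best == true_pop,
                assigned=best,
            )
        )

    rows = []
    for p in candidates:
        sub = [r for r in results if r.true_population == p]
        rows.append(
            dict(
                population=p,
                region=region_map[p],
                n=len(sub),
                correct_rate=100.0 * np.mean([r.correct for r in sub]) if sub else np.nan,
            )
        )
    pop_rates = pd.DataFrame(rows)
    region_rates: dict[str, float] = {}
    for region in REGIONS:
        sub = [r for r in results if region_map[r.true_population] == region]
        if sub:
            region_rates[region] = 100.0 * float(
                np.mean([r.best_region == region for r in sub])
            )
    return results, pop_rates, region_rates


def assign_query(
    reference: STRGenotypeTable,
    queries: STRGenotypeTable,
    score_threshold: float = 80.0,
    min_pop_size: int = 16,
) -> list[AssignmentResult]:
    """Assign query profiles against a reference database (no leave-one-out).

    Queries whose top score falls below ``score_threshold`` (percent) are
    reported as unassigned.
    """
    unknown = set(queries.loci) - set(reference.loci)
    if unknown:
        raise ValueError(f"query loci absent from reference: {sorted(unknown)}")
    counts = reference.pop_counts()
    candidates = sorted(p for p, c in counts.items() if c >= min_pop_size)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate populations after size exclusion")
    region_map = reference.populations.region_map()
    per_locus_all = _reference_arrays(reference, candidates)
    wanted = [ref for ref in per_locus_all if ref["locus"] in queries.loci]

    results = []
    for i, ind in enumerate(queries.individuals):
        genotypes = _genotypes_of(queries, i, [ref["locus"] for ref in wanted])
        if all(g is None for g in genotypes):
            raise ValueError(f"{ind}: all loci missing")
        ll = _score_individual(wanted, genotypes, candidates, loo_pop_idx=None)
        best_idx = int(np.argmax(ll))
        best = candidates[best_idx]
        scores = _scores_from_ll(ll)
        top = float(scores[best_idx])
        ok = top >= score_threshold
        results.append(
            AssignmentResult(
                ind,
                {p: float(v) for p, v in zip(candidates, ll)},
                {p: float(s) for p, s in zip(candidates, scores)},
                best,
                region_map[best],
                assigned=best if ok else None,
                status="assigned" if ok else UNASSIGNED,
            )
        )
    return results
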