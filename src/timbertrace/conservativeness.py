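"""Conservativeness testing of a pooled national database.

For each complete profile the regional profile frequency (P_origin,
computed against that region's own frequency database and its regional
theta/f) is compared with the pooled national frequency (P_combined,
national database with the national theta/f):

    d = log10(P_origin / P_combined)

The pooled database is conservative for a profile when d < 0, i.e. the
pooled database never understates the profile's frequency.  When a share
of profiles is non-conservative, theta for the pooled calculation is
raised on a grid (default step 0.01) — recomputing only P_combined —
until every test in the region yields a negative d.  The full trace
(theta -> mean d, proportion negative, mean profile frequency) is kept
for reporting.

Individuals, not unique profiles, are the test units; populations below a
minimum sample size (default 16) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import REGIONS, STRGenotypeTable
from .str_stats import AlleleFrequencyDatabase, allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class ConservativenessResult:
    profiles: pd.DataFrame  # individual, region, population, P_origin, P_combined, d
    summary: dict[str, dict[str, float]]  # region -> mean_d, proportion_negative, ...
    theta_combined: float
    f_combined: float
    theta_regional: dict[str, float]
    f_regional: dict[str, float]


@dataclass
class ThetaSweepResult:
    trace: pd.DataFrame  # region, theta, mean_d, proportion_negative, mean_profile_frequency
    adjusted_theta: dict[str, float | None]  # first grid value with all d < 0 (None = failed)
    theta_grid: np.ndarray


def _profile_arrays(
    table: STRGenotypeTable, idx: np.ndarray, freqs: AlleleFrequencyDatabase
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-profile per-locus (p1, p2, hom) arrays under a frequency database."""
    n = len(idx)
    L = len(freqs.loci)
    p1 = np.empty((n, L))
    p2 = np.empty((n, L))
    hom = np.empty((n, L), dtype=bool)
    jmap = [table.locus_index(l) for l in freqs.loci]
    for row, i in enumerate(idx):
        for col, j in enumerate(jmap):
            a, b = int(table.calls[i, j, 0]), int(table.calls[i, j, 1])
            p1[row, col] = freqs.freq(freqs.loci[col], a)
            p2[row, col] = freqs.freq(freqs.loci[col], b)
            hom[row, col] = a == b
    return p1, p2, hom


def _log10_profile_freq(
    p1: np.ndarray, p2: np.ndarray, hom: np.ndarray, theta: float, f: float
) -> tuple[np.ndarray, np.ndarray]:
    """(log10 per-profile frequency, per-locus matrix) under the match model."""
    t = theta
    hom_val = ((2 * t + (1 - t) * p1) / (1 + t)) * (
        f + (1 - f) * (3 * t + (1 - t) * p1) / (1 + 2 * t)
    )
    het_val = (
        2.0 * (1 - f)
        * ((t + (1 - t) * p1) / (1 + t))
        * ((t + (1 - t) * p2) / (1 + 2 * t))
    )
    per_locus = np.where(hom, hom_val, het_val)
    return np.log10(per_locus).sum(axis=1), per_locus


def _eligible_indices(table: STRGenotypeTable, min_pop_size: int) -> np.ndarray:
    counts = table.pop_counts()
    small = {p for p, c in counts.items() if c < min_pop_size}
    if small:
        logger.info("excluding populations below n=%d: %s", min_pop_size, sorted(small))
    keep = ~np.isin(table.population, sorted(small))
    complete = table.complete_mask()
    return np.flatnonzero(keep & complete)


def conservativeness_test(
    table: STRGenotypeTable,
    theta_combined: float,
    f_combined: float,
    theta_regional: Mapping[str, float],
    f_regional: Mapping[str, float],
    min_pop_size: int = 16,
) -> ConservativenessResult:
    """d-statistic test of every eligible complete profile.

    P_origin uses the profile's regional frequency database with the
    region's (theta, f); P_combined uses the national database with
    (theta_combined, f_combined).
    """
    idx = _eligible_indices(table, min_pop_size)
    if idx.size == 0:
        raise ValueError("no eligible complete profiles")
    regions = table.region()
    national = allele_frequencies(table, pool=None, pool_label="Malaysia")

    rows = []
    summary: dict[str, dict[str, float]] = {}
    for region in REGIONS:
        ridx = idx[regions[idx] == region]
        if ridx.size == 0:
            raise ValueError(f"region {region} has zero eligible profiles")
        regional = allele_frequencies(table, pool=region, pool_label=region)
        p1o, p2o, homo = _profile_arrays(table, ridx, regional)
        p1c, p2c, homc = _profile_arrays(table, ridx, national)
        log_po, _ = _log10_profile_freq(p1o, p2o, homo, theta_regional[region], f_regional[region])
        log_pc, _ = _log10_profile_freq(p1c, p2c, homc, theta_combined, f_combined)
        d = log_po - log_pc
        for k, i in enumerate(ridx):
            rows.append(
                dict(
                    individual=table.individuals[i],
                    population=int(table.population[i]),
                    region=region,
                    P_origin=10.0 ** log_po[k],
                    P_combined=10.0 ** log_pc[k],
                    d=float(d[k]),
                )
            )
        summary[region] = dict(
            n_tests=int(ridx.size),
            mean_d=float(d.mean()),
            proportion_negative=float((d < 0).mean()),
            mean_P_origin=float(np.mean(10.0 ** log_po)),
            mean_P_combined=float(np.mean(10.0 ** log_pc)),
        )
    return ConservativenessResult(
        pd.DataFrame(rows),
        summary,
        theta_combined,
        f_combined,
        dict(theta_regional),
        dict(f_regional),
    )


def theta_sweep(
    table: STRGenotypeTable,
    theta_start: float,
    f_combined: float,
    theta_regional: Mapping[str, float],
    f_regional: Mapping[str, float],
    step: float = 0.01,
    theta_max: float = 0.5,
    min_pop_size: int = 16,
) -> ThetaSweepResult:
    """Raise the pooled-database theta until every d is negative, per region.

    Only P_combined is recomputed along the sweep; P_origin is fixed at the
    regional databases' values.  Returns the first grid value achieving
    100% negative d per region (None, flagged, if theta_max is reached
    without success) plus the full trace.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    idx = _eligible_indices(table, min_pop_size)
    if idx.size == 0:
        raise ValueError("no eligible complete profiles")
    regions = table.region()
    national = allele_frequencies(table, pool=None, pool_label="Malaysia")
    grid = np.arange(theta_start, theta_max + step / 2, step)

    rows = []
    adjusted: dict[str, float | None] = {}
    for region in REGIONS:
        ridx = idx[regions[idx] == region]
        if ridx.size == 0:
            continue
        regional = allele_frequencies(table, pool=region, pool_label=region)
        p1o, p2o, homo = _profile_arrays(table, ridx, regional)
        p1c, p2c, homc = _profile_arrays(table, ridx, national)
        log_po, _ = _log10_profile_freq(p1o, p2o, homo, theta_regional[region], f_regional[region])
        adjusted[region] = None
        for theta in grid:
            log_pc, _ = _log10_profile_freq(p1c, p2c, homc, float(theta), f_combined)
            d = log_po - log_pc
            prop_neg = float((d < 0).mean())
            rows.append(
                dict(
                    region=region,
                    theta=float(theta),
                    mean_d=float(d.mean()),
                    proportion_negative=prop_neg,
                    mean_profile_frequency=float(np.mean(10.0 ** log_pc)),
                )
            )
            if prop_neg == 1.0:
                adjusted[region] = float(theta)
                break
        if adjusted[region] is None:
            logger.warning(
                "%s: sweep reached theta_max=%.2f without full conservativeness", region, theta_max
            )
    return ThetaSweepResult(pd.DataFrame(rows), adjusted, grid)
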