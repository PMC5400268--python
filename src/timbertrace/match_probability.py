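"""Genotype and multilocus profile frequencies under the
subpopulation-cum-inbreeding model.

The match-probability form conditions on having already seen the profile
once (Balding-Nichols sampling formulas for a subdivided population with
coancestry theta), with within-population inbreeding f entering as an
identity-by-descent mixture at the second allele draw:

    homozygote   P = [2t + (1-t)p] / (1+t) * ( f + (1-f) [3t + (1-t)p] / (1+2t) )
    heterozygote P = 2 (1-f) [t + (1-t)p_i] / (1+t) * [t + (1-t)p_j] / (1+2t)

At f = 0 these are the Balding-Nichols match probabilities; at
theta = f = 0 they reduce to Hardy-Weinberg products.  The unconditional
mode gives ordinary single-draw genotype frequencies (hom p^2 + f p(1-p),
het 2 p_i p_j (1-f)), which sum to one over all genotypes at a locus.

Profile frequency is the product of per-locus genotype frequencies over a
complete (no missing data) profile, computed against floored database
frequencies; its reciprocal is the random match probability statement
"1 in X".  Heterozygote match-mode values can fall below 2 p_i p_j for
common alleles — a property of the model, not an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, STRGenotypeTable
from .str_stats import AlleleFrequencyDatabase

logger = logging.getLogger(__name__)


class IncompleteProfileError(ValueError):
    """Raised when a profile has a missing call at a database locus."""


def _validate(p: float, name: str = "p") -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"{name} must lie in (0, 1]; got {p}")


def genotype_frequency(
    p_i: float,
    p_j: float,
    theta: float = 0.0,
    f: float = 0.0,
    mode: str = "match",
    homozygous: bool | None = None,
) -> float:
    """Genotype frequency for alleles with frequencies p_i, p_j.

    ``homozygous`` states whether the two alleles are the same allele; when
    omitted it is inferred from frequency equality, which is only safe when
    distinct alleles never share a frequency — callers scoring real
    genotypes should pass it explicitly.  ``mode`` selects the conditional
    match-probability form (default, used throughout the pipeline) or the
    unconditional single-draw form.
    """
    _validate(p_i, "p_i")
    _validate(p_j, "p_j")
    if not (0.0 <= theta < 1.0):
        raise ValueError(f"theta must lie in [0, 1); got {theta}")
    if not (0.0 <= f < 1.0):
        raise ValueError(f"f must lie in [0, 1); got {f}")
    hom = (p_i == p_j) if homozygous is None else homozygous
    if mode == "match":
        t = theta
        if hom:
            p = p_i
            first = (2 * t + (1 - t) * p) / (1 + t)
            second = f + (1 - f) * (3 * t + (1 - t) * p) / (1 + 2 * t)
            return first * second
        return (
            2.0
            * (1 - f)
            * ((t + (1 - t) * p_i) / (1 + t))
            * ((t + (1 - t) * p_j) / (1 + 2 * t))
        )
    if mode == "unconditional":
        if hom:
            p = p_i
            return p * p + f * p * (1 - p)
        return 2.0 * p_i * p_j * (1 - f)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ProfileFrequencyResult:
    individual_id: str
    per_locus: dict[str, float]
    profile_frequency: float
    rmp_reciprocal: float
    theta_used: float
    f_used: float
    pool_label: str

    def log10_profile_frequency(self) -> float:
        return math.fsum(math.log10(v) for v in self.per_locus.values())


def profile_frequency(
    profile: dict[str, tuple[int, int]],
    freqs: AlleleFrequencyDatabase,
    theta: float = 0.0,
    f: float = 0.0,
    individual_id: str = "query",
) -> ProfileFrequencyResult:
    """Multilocus profile frequency against a floored frequency database.

    The profile must be complete at every database locus; alleles absent
    from the database contribute at the frequency floor.
    """
    per_locus: dict[str, float] = {}
    for locus in freqs.loci:
        if locus not in profile:
            raise IncompleteProfileError(
                f"{individual_id}: no call at database locus {locus}"
            )
        a, b = profile[locus]
        if a == MISSING or b == MISSING:
            raise IncompleteProfileError(
                f"{individual_id}: missing call at locus {locus}; "
                "profile frequencies require complete profiles"
            )
        p_a = freqs.freq(locus, a)
        if a == b:
            g = genotype_frequency(p_a, p_a, theta, f, mode="match", homozygous=True)
        else:
            p_b = freqs.freq(locus, b)
            g = genotype_frequency(p_a, p_b, theta, f, mode="match", homozygous=False)
        per_locus[locus] = g
    pf = float(np.prod(list(per_locus.values())))
    return ProfileFrequencyResult(
        individual_id,
        per_locus,
        pf,
        math.inf if pf == 0 else 1.0 / pf,
        theta,
        f,
        freqs.pool_label,
    )


def table_profiles(table: STRGenotypeTable, loci: list[str] | None = None):
    """Iterate (individual_id, profile dict) rows of a genotype table."""
    loci = loci if loci is not None else table.loci
    idx = [table.locus_index(l) for l in loci]
    for i, ind in enumerate(table.individuals):
        yield ind, {l: (int(table.calls[i, j, 0]), int(table.calls[i, j, 1])) for l, j in zip(loci, idx)}


def profile_frequencies_table(
    table: STRGenotypeTable,
    freqs: AlleleFrequencyDatabase,
    theta: float = 0.0,
    f: float = 0.0,
    skip_incomplete: bool = True,
) -> pd.DataFrame:
    """Per-individual profile frequencies and reciprocals as a table."""
    rows = []
    for ind, profile in table_profiles(table, freqs.loci):
        try:
            res = profile_frequency(profile, freqs, theta, f, individual_id=ind)
        except IncompleteProfileError:
            if skip_incomplete:
                continue
            raise
        rows.append(
            dict(
                individual=ind,
                profile_frequency=res.profile_frequency,
                rmp_reciprocal=res.rmp_reciprocal,
                log10_profile_frequency=res.log10_profile_frequency(),
            )
        )
    return pd.DataFrame(rows)
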