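"""Chloroplast haplotype database for geographic-origin inference.

Haplotypes are multilocus state vectors over the informative variable sites
(nucleotide substitutions and indel events) of a panel of intergenic
spacers.  Because chloroplast DNA is maternally inherited it is strongly
geographically structured, so region-confined haplotypes carry origin
information: a query carrying a haplotype confined to one region is
attributed to that region, a shared haplotype is ambiguous, and a haplotype
absent from the database is novel (no attribution).

Indels use simple coding: one contiguous gap event, regardless of length,
is one binary presence/absence character.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core_io import EASTERN, REGIONS, WESTERN, PopulationTable, SequenceAlignment

logger = logging.getLogger(__name__)

UNKNOWN_STATE = "?"
GAP_PRESENT = "+"  # bases present at an indel event
GAP_ABSENT = "-"   # deletion state at an indel event

NOVEL = "NOVEL"
AMBIGUOUS = "ambiguous"
NO_REGION = "none"


class Site(NamedTuple):
    region_name: str
    column: int  # 0-based column of the site (first column for an indel run)
    kind: str    # "substitution" | "indel"


@dataclass
class VariableSiteMatrix:
    """Per-sample states at every informative variable site.

    ``states`` is an ``(n_samples, n_sites)`` array of single characters:
    a nucleotide for substitutions, ``+``/``-`` for indel events, and ``?``
    where a sample's state could not be determined (ambiguous base).
    """

    sites: list[Site]
    samples: list[str]
    states: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.shape != (len(self.samples), len(self.sites)):
            raise ValueError("states shape mismatch")
        for j in range(len(self.sites)):
            observed = {s for s in self.states[:, j] if s != UNKNOWN_STATE}
            if len(observed) < 2:
                raise ValueError(f"site {self.sites[j]} is not variable")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def vector(self, sample: str) -> str:
        i = self.samples.index(sample)
        return "".join(self.states[i])

    def site_counts(self) -> dict[str, int]:
        c = Counter(s.kind for s in self.sites)
        return {"substitution": c.get("substitution", 0), "indel": c.get("indel", 0)}


@dataclass
class HaplotypeDatabase:
    """Haplotype key table with per-population occurrence and region status."""

    haplotypes: dict[str, str]           # ID -> state vector
    occurrence: dict[str, dict[int, int]]  # ID -> {population code: count}
    region_status: dict[str, str]        # ID -> "confined:Western" | "confined:Eastern" | "shared"
    unique_flag: dict[str, bool]         # ID -> found in a single population only
    sites: list[Site]
    n_samples: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def count(self, hap_id: str) -> int:
        return sum(self.occurrence[hap_id].values())

    def key_table(self) -> pd.DataFrame:
        rows = []
        for hid, vec in self.haplotypes.items():
            rows.append(
                dict(
                    haplotype=hid,
                    states=vec,
                    count=self.count(hid),
                    region_status=self.region_status[hid],
                    unique=self.unique_flag[hid],
                    populations=",".join(str(p) for p in sorted(self.occurrence[hid])),
                )
            )
        return pd.DataFrame(rows)

    def occurrence_matrix(self) -> pd.DataFrame:
        """Per-population haplotype count table (populations x haplotypes)."""
        pops = sorted({p for occ in self.occurrence.values() for p in occ})
        data = {hid: [self.occurrence[hid].get(p, 0) for p in pops] for hid in self.haplotypes}
        return pd.DataFrame(data, index=pops)


@dataclass
class HaplotypeCall:
    sample_id: str
    matched: str  # haplotype ID or NOVEL
    inferred_region: str  # Western | Eastern | ambiguous | none

    def __post_init__(self):
        if self.matched == NOVEL and self.inferred_region != NO_REGION:
            raise ValueError("novel haplotypes carry no region inference")


# ---------------------------------------------------------------------------
# Variable-site extraction
# ---------------------------------------------------------------------------


def extract_variable_sites(alignments: Sequence[SequenceAlignment]) -> VariableSiteMatrix:
    """Concatenate the informative variable sites of a set of alignments.

    Substitution sites are columns (outside indel runs) with at least two
    distinct unambiguous bases.  Contiguous runs of gap-containing columns
    are collapsed into a single indel event whose states are presence (+) /
    absence (-) of the spanned bases; a sample that is partially gapped or
    ambiguous within the run gets an unknown state.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    sample_ids = alignments[0].sample_ids
    sample_set = set(sample_ids)
    for aln in alignments[1:]:
        if set(aln.sample_ids) != sample_set:
            extra = set(aln.sample_ids) ^ sample_set
            raise ValueError(
                f"sample sets differ between {alignments[0].region_name} and "
                f"{aln.region_name}: {sorted(extra)[:5]}"
            )

    sites: list[Site] = []
    columns: list[np.ndarray] = []
    for aln in alignments:
        mat = np.array([list(aln.records[s]) for s in sample_ids], dtype="<U1")
        has_gap = (mat == "-").any(axis=0)
        # group consecutive gap-bearing columns into indel events
        events: list[tuple[int, int]] = []
        start = None
        for j in range(mat.shape[1] + 1):
            inside = j < mat.shape[1] and has_gap[j]
            if inside and start is None:
                start = j
            elif not inside and start is not None:
                events.append((start, j))
                start = None
        event_cols = np.zeros(mat.shape[1], dtype=bool)
        local: list[tuple[Site, np.ndarray]] = []
        for a, b in events:
            event_cols[a:b] = True
            block = mat[:, a:b]
            state = np.full(len(sample_ids), UNKNOWN_STATE, dtype="<U1")
            all_gap = (block == "-").all(axis=1)
            no_gap = (block != "-").all(axis=1)
            clean = ~(block == "N").any(axis=1)
            state[all_gap] = GAP_ABSENT
            state[no_gap & clean] = GAP_PRESENT
            observed = {s for s in state if s != UNKNOWN_STATE}
            if len(observed) >= 2:
                local.append((Site(aln.region_name, a, "indel"), state))
        for j in range(mat.shape[1]):
            if event_cols[j]:
                continue
            col = mat[:, j].copy()
            col[col == "N"] = UNKNOWN_STATE
            observed = {s for s in col if s != UNKNOWN_STATE}
            if len(observed) >= 2:
                local.append((Site(aln.region_name, j, "substitution"), col))
        local.sort(key=lambda t: t[0].column)
        for site, state in local:
            sites.append(site)
            columns.append(state)

    if not sites:
        raise ValueError("no variable sites found")
    states = np.stack(columns, axis=1)
    logger.info(
        "extracted %d variable sites (%d substitutions, %d indels) from %d samples",
        len(sites),
        sum(s.kind == "substitution" for s in sites),
        sum(s.kind == "indel" for s in sites),
        len(sample_ids),
    )
    return VariableSiteMatrix(sites, list(sample_ids), states)


# ---------------------------------------------------------------------------
# Haplotype collapse and classification
# ---------------------------------------------------------------------------


def collapse_haplotypes(
    matrix: VariableSiteMatrix,
    sample_populations: Mapping[str, int],
    populations: PopulationTable,
    max_unknown_fraction: float = 0.5,
) -> HaplotypeDatabase:
    """Collapse identical state vectors into numbered haplotypes.

    IDs (H1, H2, ...) are assigned by descending total count, ties broken by
    first sample occurrence — presentation-only ordering.  A haplotype is
    flagged unique when observed in a single population.
    """
    if matrix.n_sites == 0 or not matrix.samples:
        raise ValueError("empty variable-site matrix")
    missing = [s for s in matrix.samples if s not in sample_populations]
    if missing:
        raise KeyError(f"samples without population assignment: {missing[:5]}")

    region_map = populations.region_map()
    groups: dict[str, list[int]] = defaultdict(list)
    for i, _ in enumerate(matrix.samples):
        vec = "".join(matrix.states[i])
        unk = vec.count(UNKNOWN_STATE) / len(vec)
        if unk > max_unknown_fraction:
            raise ValueError(
                f"sample {matrix.samples[i]!r} has unknown state at {unk:.0%} of sites"
            )
        groups[vec].append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    haplotypes: dict[str, str] = {}
    occurrence: dict[str, dict[int, int]] = {}
    region_status: dict[str, str] = {}
    unique_flag: dict[str, bool] = {}
    for rank, (vec, idxs) in enumerate(ordered, start=1):
        hid = f"H{rank}"
        haplotypes[hid] = vec
        occ: Counter = Counter(int(sample_populations[matrix.samples[i]]) for i in idxs)
        occurrence[hid] = dict(occ)
        regions = {region_map[p] for p in occ}
        if regions == {WESTERN}:
            region_status[hid] = f"confined:{WESTERN}"
        elif regions == {EASTERN}:
            region_status[hid] = f"confined:{EASTERN}"
        else:
            region_status[hid] = "shared"
        unique_flag[hid] = len(occ) == 1

    return HaplotypeDatabase(
        haplotypes, occurrence, region_status, unique_flag, list(matrix.sites), len(matrix.samples)
    )


def classify_haplotype(
    db: HaplotypeDatabase,
    states: str | Sequence[str],
    sample_id: str = "query",
    max_unknown: int = 0,
) -> HaplotypeCall:
    """Exact-match lookup of a state vector against the database.

    Up to ``max_unknown`` unknown sites are tolerated when exactly one
    database haplotype completes them (unique-completion matching); the
    default is strict (0), the forensically cautious setting.  Anything
    else is NOVEL with no region inference.
    """
    vec = "".join(states)
    if len(vec) != db.n_sites:
        raise ValueError(f"state vector length {len(vec)} != database site count {db.n_sites}")
    n_unknown = vec.count(UNKNOWN_STATE)
    matched = NOVEL
    if n_unknown == 0:
        for hid, hvec in db.haplotypes.items():
            if hvec == vec:
                matched = hid
                break
    elif n_unknown <= max_unknown:
        known = [i for i, c in enumerate(vec) if c != UNKNOWN_STATE]
        candidates = [
            hid for hid, hvec in db.haplotypes.items() if all(hvec[i] == vec[i] for i in known)
        ]
        if len(candidates) == 1:
            matched = candidates[0]

    if matched == NOVEL:
        return HaplotypeCall(sample_id, NOVEL, NO_REGION)
    status = db.region_status[matched]
    if status == "shared":
        region = AMBIGUOUS
    else:
        region = status.split(":", 1)[1]
    return HaplotypeCall(sample_id, matched, region)


def summarize_region_origin(calls: Sequence[HaplotypeCall]) -> dict[str, float]:
    """Percentage of samples attributable to each region by confinement.

    Shared-haplotype (ambiguous) and novel calls count as unattributed.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    n = len(calls)
    counts = Counter(c.inferred_region for c in calls)
    out = {region: 100.0 * counts.get(region, 0) / n for region in REGIONS}
    out["unattributed"] = 100.0 * (counts.get(AMBIGUOUS, 0) + counts.get(NO_REGION, 0)) / n
    return out
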