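"""Synthetic STR and chloroplast datasets with the statistical structure the
analysis assumes.

The STR generator is a hierarchical Dirichlet (Balding-Nichols) model: a
national ancestral frequency vector per locus, a regional layer adding
cross-region divergence, population frequencies drawn around their
region's ancestral vector with the region's coancestry theta, and diploid
genotypes drawn with within-population inbreeding f as an
identity-by-descent mixture.  This is exactly the model under which the
theta-corrected match probabilities are derived, which makes parameter
recovery a fair, non-circular test of the estimators.

Defaults reproduce the reference study design: 27 populations in two
regions with the published sample sizes (1032 individuals), 15 loci with
12-31 alleles, regional coancestry 0.0333 (Western) / 0.1064 (Eastern)
and inbreeding 0.0358 / 0.1248.

The chloroplast generator constructs 29 distinct haplotypes over 39
variable sites (31 substitutions + 8 indel events) embedded in seven
spacer alignments of the published lengths, placed across populations so
that one widespread haplotype is confined to Western populations at 57.5%
of samples, exactly two haplotypes occur in both regions, and 16
haplotypes are singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    EASTERN,
    MISSING,
    WESTERN,
    PopulationTable,
    STRGenotypeTable,
    SequenceAlignment,
    STR_PANEL,
    malaysia_reference_populations,
)
from .haplotype_db import HaplotypeCall, classify_haplotype, collapse_haplotypes, extract_variable_sites

logger = logging.getLogger(__name__)

#: Spacer name, alignment length (bp), variable sites and indels hosted.
SPACERS = [
    ("trnT-trnL", 314, 2, 0),
    ("trnS-trnG", 277, 8, 2),
    ("atpB-rbcL", 531, 5, 1),
    ("petG-trnP", 449, 3, 1),
    ("trnG-atpA", 362, 5, 1),
    ("psbM-trnD", 559, 11, 2),
    ("trnG-rps14", 400, 5, 1),
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the STR simulator."""

    populations: PopulationTable = field(default_factory=malaysia_reference_populations)
    n_loci: int = 15
    locus_names: list[str] = field(default_factory=lambda: list(STR_PANEL))
    allele_range: tuple[int, int] = (12, 31)
    alleles_per_locus: list[int] | None = None  # drawn from allele_range when None
    theta_region: dict[str, float] = field(
        default_factory=lambda: {WESTERN: 0.0333, EASTERN: 0.1064}
    )
    f_region: dict[str, float] = field(
        default_factory=lambda: {WESTERN: 0.0358, EASTERN: 0.1248}
    )
    #: divergence of each region's ancestral pool from the national pool;
    #: 0.10 makes the pooled national coancestry estimate come out near the
    #: study's 0.06 given the two regional theta values (the pooled estimate
    #: is dominated by the large Western stratum, so the between-region layer
    #: must be markedly larger than the within-region ones)
    theta_between: float = 0.10
    missing_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self):
        for d in (self.theta_region, self.f_region):
            for region, v in d.items():
                if not (0.0 <= v < 1.0):
                    raise ValueError(f"{region}: theta/f must lie in [0, 1); got {v}")
        if not (0.0 <= self.theta_between < 1.0):
            raise ValueError("theta_between must lie in [0, 1)")
        if "n_ind" in self.populations.frame.columns:
            if (self.populations.frame["n_ind"] < 1).any():
                raise ValueError("population sizes must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible simulation")
        if len(self.locus_names) != self.n_loci:
            self.locus_names = [f"L{i+1:03d}" for i in range(self.n_loci)]


def _dirichlet_around(rng: np.random.Generator, base: np.ndarray, theta: float) -> np.ndarray:
    """Draw a frequency vector centred on ``base`` with divergence theta."""
    if theta == 0.0:
        return base.copy()
    conc = np.maximum(base, 1e-9) * (1.0 - theta) / theta
    draw = rng.dirichlet(conc)
    return np.maximum(draw, 1e-12) / np.maximum(draw, 1e-12).sum()


def simulate_str_dataset(config: SimulationConfig) -> tuple[STRGenotypeTable, dict]:
    """Simulate a diploid STR genotype table plus a truth record.

    The truth record stores all latent frequencies (ancestral, regional,
    per-population) and the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.populations
    frame = pops.frame
    codes = [int(c) for c in frame["code"]]
    sizes = {int(c): int(n) for c, n in zip(frame["code"], frame["n_ind"])}
    region_map = pops.region_map()

    lo, hi = config.allele_range
    if config.alleles_per_locus is not None:
        A = list(config.alleles_per_locus)
        if len(A) != config.n_loci:
            raise ValueError("alleles_per_locus length mismatch")
    else:
        A = rng.integers(lo, hi + 1, size=config.n_loci).tolist()

    # allele labels: plausible fragment sizes, distinct 2-bp ladder per locus
    allele_labels = []
    for j in range(config.n_loci):
        start = int(rng.integers(100, 220))
        allele_labels.append(np.arange(start, start + 2 * A[j], 2, dtype=np.int64))

    regions = sorted(set(region_map.values()))
    ancestral = []
    regional: dict[str, list[np.ndarray]] = {r: [] for r in regions}
    pop_freqs: dict[int, list[np.ndarray]] = {c: [] for c in codes}
    for j in range(config.n_loci):
        p0 = rng.dirichlet(np.ones(A[j]))
        p0 = np.maximum(p0, 1e-9) / np.maximum(p0, 1e-9).sum()
        ancestral.append(p0)
        for r in regions:
            regional[r].append(_dirichlet_around(rng, p0, config.theta_between))
        for c in codes:
            r = region_map[c]
            pop_freqs[c].append(_dirichlet_around(rng, regional[r][j], config.theta_region[r]))

    individuals: list[str] = []
    population: list[int] = []
    rows = []
    for c in codes:
        n = sizes[c]
        r = region_map[c]
        f = config.f_region[r]
        calls = np.zeros((n, config.n_loci, 2), dtype=np.int64)
        for j in range(config.n_loci):
            labels = allele_labels[j]
            p = pop_freqs[c][j]
            first = rng.choice(len(p), size=n, p=p)
            second = rng.choice(len(p), size=n, p=p)
            ibd = rng.random(n) < f
            second[ibd] = first[ibd]
            calls[:, j, 0] = labels[first]
            calls[:, j, 1] = labels[second]
        if config.missing_rate > 0:
            miss = rng.random((n, config.n_loci)) < config.missing_rate
            calls[miss] = MISSING
        rows.append(calls)
        individuals.extend(f"P{c:02d}-{i+1:03d}" for i in range(n))
        population.extend([c] * n)

    table = STRGenotypeTable(
        individuals,
        list(config.locus_names),
        np.concatenate(rows, axis=0),
        np.array(population, dtype=np.int64),
        pops,
    )
    truth = dict(
        seed=config.seed,
        alleles_per_locus=A,
        allele_labels=[l.tolist() for l in allele_labels],
        ancestral=[p.tolist() for p in ancestral],
        regional={r: [p.tolist() for p in regional[r]] for r in regions},
        population_freqs={c: [p.tolist() for p in pop_freqs[c]] for c in codes},
        theta_region=dict(config.theta_region),
        f_region=dict(config.f_region),
        theta_between=config.theta_between,
        missing_rate=config.missing_rate,
    )
    logger.info("simulated %d individuals x %d loci", table.n_individuals, table.n_loci)
    return table, truth


# ---------------------------------------------------------------------------
# Chloroplast haplotype simulation
# ---------------------------------------------------------------------------


def _descending_split(total: int, parts: int, minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` descending integers, each >= minimum."""
    if parts == 0:
        if total:
            raise ValueError("cannot place samples into zero haplotypes")
        return []
    if total < parts * minimum:
        raise ValueError(f"cannot split {total} into {parts} parts of >= {minimum}")
    vals = [minimum] * parts
    rem = total - parts * minimum
    i = 0
    while rem > 0:
        vals[i % parts] += 1
        rem -= 1
        i += 1
    return sorted(vals, reverse=True)


def simulate_cpdna_dataset(
    seed: int,
    populations: PopulationTable | None = None,
    n_substitutions: int = 31,
    n_indels: int = 8,
    n_haplotypes: int = 29,
    widespread_western_fraction: float = 0.575,
    shared_haplotypes: int = 2,
    n_singletons: int = 16,
    n_eastern_confined: int = 8,
) -> tuple[list[SequenceAlignment], dict]:
    """Construct spacer alignments realizing a target haplotype geography.

    Returns the seven alignments plus a truth record (haplotype state
    vectors, per-sample haplotype assignment, per-population composition).
    Raises on infeasible configurations (e.g. more region-confined
    haplotypes than the region can host).
    """
    rng = np.random.default_rng(seed)
    pops = populations if populations is not None else malaysia_reference_populations()
    frame = pops.frame
    sizes = {int(c): int(n) for c, n in zip(frame["code"], frame["n_pop"])}
    region_map = pops.region_map()
    west_pops = [c for c in sizes if region_map[c] == WESTERN]
    east_pops = [c for c in sizes if region_map[c] == EASTERN]
    MW = sum(sizes[c] for c in west_pops)
    ME = sum(sizes[c] for c in east_pops)
    M = MW + ME
    n_sites = n_substitutions + n_indels
    if n_haplotypes > 2**n_sites:
        raise ValueError("more haplotypes than distinct site-state vectors")

    # ---- haplotype count plan ------------------------------------------------
    if n_haplotypes == 1:
        hap_counts = [M]
        assignment_plan = {0: {c: sizes[c] for c in sizes}}
    else:
        h1 = int(round(widespread_western_fraction * M))
        if h1 > MW:
            raise ValueError("widespread western haplotype exceeds western capacity")
        if shared_haplotypes > 0 and ME < shared_haplotypes:
            raise ValueError("eastern capacity below shared haplotype count")
        east_multi = min(3, n_eastern_confined)
        east_singles = n_eastern_confined - east_multi
        if east_singles > n_singletons:
            raise ValueError("eastern singleton demand exceeds singleton budget")
        west_singles = n_singletons - east_singles
        # eastern shares of the shared haplotypes: the first takes a third of
        # the region, the rest one sample each
        if shared_haplotypes > 0:
            shared_east = [max(1, ME // 3)] + [1] * (shared_haplotypes - 1)
        else:
            shared_east = []
        east_conf_total = ME - sum(shared_east) - east_singles
        east_multi_counts = _descending_split(east_conf_total, east_multi, 2) if east_multi else []
        if east_multi == 0 and east_conf_total:
            raise ValueError("eastern samples left over with no eastern-confined haplotype")

        n_west_multi = n_haplotypes - 1 - shared_haplotypes - n_eastern_confined - west_singles
        if n_west_multi < 0:
            raise ValueError("haplotype budget too small for the confinement plan")
        shared_total = []
        if shared_haplotypes > 0:
            # second-commonest haplotype overall is the first shared one
            c2 = max(int(round(0.131 * M)), shared_east[0] + 1)
            shared_total = [c2] + [se + 2 for se in shared_east[1:]]
        west_multi_total = (
            MW
            - h1
            - sum(st - se for st, se in zip(shared_total, shared_east))
            - west_singles
        )
        west_multi_counts = (
            _descending_split(west_multi_total, n_west_multi, 2) if n_west_multi else []
        )
        if n_west_multi == 0 and west_multi_total:
            raise ValueError("western samples left over with no western-confined haplotype")

        # assemble (count, kind) and order by descending count
        entries: list[tuple[int, str, int | None]] = [(h1, "west_widespread", None)]
        for i, st in enumerate(shared_total):
            entries.append((st, "shared", shared_east[i]))
        for cnt in west_multi_counts:
            entries.append((cnt, "west", None))
        for cnt in east_multi_counts:
            entries.append((cnt, "east", None))
        entries.sort(key=lambda e: -e[0])
        for _ in range(west_singles):
            entries.append((1, "west", None))
        for _ in range(east_singles):
            entries.append((1, "east", None))
        if len(entries) != n_haplotypes:
            raise ValueError("haplotype plan inconsistent with n_haplotypes")
        hap_counts = [e[0] for e in entries]
        if sum(hap_counts) != M:
            raise ValueError("haplotype counts do not cover the sample")

        # ---- deal haplotypes into populations --------------------------------
        west_capacity = {c: sizes[c] for c in west_pops}
        east_capacity = {c: sizes[c] for c in east_pops}
        assignment_plan: dict[int, dict[int, int]] = {i: {} for i in range(len(entries))}

        def deal(hap_idx: int, count: int, capacity: dict[int, int], spread: bool):
            order = sorted(capacity, key=lambda c: (-capacity[c], c))
            if spread:  # at least one sample in every population of the region
                for c in order:
                    if count == 0:
                        break
                    if capacity[c] > 0:
                        assignment_plan[hap_idx][c] = assignment_plan[hap_idx].get(c, 0) + 1
                        capacity[c] -= 1
                        count -= 1
            while count > 0:
                order = sorted(capacity, key=lambda c: (-capacity[c], c))
                if capacity[order[0]] == 0:
                    raise ValueError("ran out of regional capacity")
                assignment_plan[hap_idx][order[0]] = assignment_plan[hap_idx].get(order[0], 0) + 1
                capacity[order[0]] -= 1
                count -= 1

        for idx, (count, kind, east_share) in enumerate(entries):
            if kind == "west_widespread":
                deal(idx, count, west_capacity, spread=True)
            elif kind == "west":
                deal(idx, count, west_capacity, spread=False)
            elif kind == "east":
                deal(idx, count, east_capacity, spread=False)
            else:  # shared
                deal(idx, east_share, east_capacity, spread=False)
                deal(idx, count - east_share, west_capacity, spread=False)
        if any(v for v in west_capacity.values()) or any(v for v in east_capacity.values()):
            raise ValueError("population capacity not fully used")

    # ---- haplotype state vectors --------------------------------------------
    # haplotype 0 is all-reference; site i's derived state is carried by the
    # haplotype (i mod (n-1)) + 1, giving distinct nonempty derived sets
    derived_sets: list[set[int]] = [set() for _ in range(len(hap_counts))]
    if len(hap_counts) > 1:
        for site in range(n_sites):
            owner = 1 + site % (len(hap_counts) - 1)
            derived_sets[owner].add(site)

    # ---- embed into spacer alignments ---------------------------------------
    spacer_sites: list[tuple[str, int, int]] = []  # per spacer: (name, length, n_sites here)
    subs_left, indels_left = n_substitutions, n_indels
    plan = []
    for name, length, default_sites, default_indels in SPACERS:
        if n_substitutions == 31 and n_indels == 8:
            s_here, i_here = default_sites - default_indels, default_indels
        else:
            total_def = sum(s for _, _, s, _ in SPACERS)
            share = round(n_sites * default_sites / total_def)
            i_here = min(indels_left, max(0, share // 4))
            s_here = min(subs_left, share - i_here)
        plan.append((name, length, s_here, i_here))
        subs_left -= s_here
        indels_left -= i_here
    # distribute any remainder into the last spacer
    name, length, s_here, i_here = plan[-1]
    plan[-1] = (name, length, s_here + subs_left, i_here + indels_left)

    bases = np.array(list("ACGT"))
    sample_ids: list[str] = []
    sample_pop: dict[str, int] = {}
    sample_hap: dict[str, int] = {}
    per_pop_counter: dict[int, int] = {c: 0 for c in sizes}
    ordered_codes = sorted(sizes)
    # emit samples population by population; within a population, haplotypes
    # in plan order so first-occurrence ties are deterministic
    for c in ordered_codes:
        for hap_idx in range(len(hap_counts)):
            k = assignment_plan.get(hap_idx, {}).get(c, 0)
            for _ in range(k):
                per_pop_counter[c] += 1
                sid = f"C{c:02d}-{per_pop_counter[c]:02d}"
                sample_ids.append(sid)
                sample_pop[sid] = c
                sample_hap[sid] = hap_idx

    alignments: list[SequenceAlignment] = []
    site_cursor = 0
    global_site_index: list[tuple[str, int, str]] = []
    for name, length, s_here, i_here in plan:
        ref = rng.choice(bases, size=length)
        # reserve positions: keep sites >= 6 columns apart so indel runs
        # (length 2) never merge with a neighbouring variable column
        n_here = s_here + i_here
        if n_here == 0:
            seq = "".join(ref)
            alignments.append(SequenceAlignment(name, {sid: seq for sid in sample_ids}))
            continue
        usable = length - 10
        positions = sorted(rng.choice(usable // 6, size=n_here, replace=False) * 6 + 5)
        kinds = ["indel"] * i_here + ["substitution"] * s_here
        rng.shuffle(kinds)
        site_meta = []
        for pos, kind in zip(positions, kinds):
            if kind == "substitution":
                alt = str(rng.choice([b for b in "ACGT" if b != ref[pos]]))
                site_meta.append((pos, kind, alt))
            else:
                site_meta.append((pos, kind, None))
            global_site_index.append((name, pos, kind))

        records = {}
        for sid in sample_ids:
            hap = sample_hap[sid]
            seq = ref.copy().astype("<U1")
            for offset, (pos, kind, alt) in enumerate(site_meta):
                gidx = site_cursor + offset
                if gidx in derived_sets[hap]:
                    if kind == "substitution":
                        seq[pos] = alt
                    else:
                        seq[pos] = "-"
                        seq[pos + 1] = "-"
            records[sid] = "".join(seq)
        site_cursor += n_here
        alignments.append(SequenceAlignment(name, records))

    truth = dict(
        seed=seed,
        n_sites=n_sites,
        n_substitutions=n_substitutions,
        n_indels=n_indels,
        n_haplotypes=len(hap_counts),
        hap_counts=hap_counts,
        derived_sets=[sorted(s) for s in derived_sets],
        sample_populations=sample_pop,
        sample_haplotype=sample_hap,
        site_index=global_site_index,
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# Planted-stand fixture (query workflow demo)
# ---------------------------------------------------------------------------


@dataclass
class FrimFixture:
    """A 40-sample planted-stand query set for the full workflow.

    ``haplotype_calls`` reproduce the published composition of the planted
    stand (27 samples of the commonest western haplotype, 4 of the shared
    H2, 2 of H3, 1 of H5, 6 novel); ``query_table`` holds synthetic STR
    profiles drawn from four northwestern source populations for the
    assignment demo.
    """

    haplotype_calls: list[HaplotypeCall]
    query_table: STRGenotypeTable
    truth: dict


def frim_fixture(seed: int = 0) -> FrimFixture:
    pops = malaysia_reference_populations()
    alignments, cp_truth = simulate_cpdna_dataset(seed=seed, populations=pops)
    matrix = extract_variable_sites(alignments)
    db = collapse_haplotypes(matrix, cp_truth["sample_populations"], pops)

    composition = [("H1", 27), ("H2", 4), ("H3", 2), ("H5", 1)]
    calls: list[HaplotypeCall] = []
    i = 0
    for hid, count in composition:
        vec = db.haplotypes[hid]
        for _ in range(count):
            i += 1
            calls.append(classify_haplotype(db, vec, sample_id=f"FRIM-{i:02d}"))
    # six novel vectors: pairs of derived states never combined in the database
    known = set(db.haplotypes.values())
    ref_vec = db.haplotypes["H1"]
    site_alts = []
    for j in range(db.n_sites):
        alts = {v[j] for v in db.haplotypes.values()} - {ref_vec[j]}
        site_alts.append(sorted(alts)[0] if alts else None)
    novel_added = 0
    j = 0
    while novel_added < 6 and j + 1 < db.n_sites:
        if site_alts[j] is not None and site_alts[j + 1] is not None:
            vec = list(ref_vec)
            vec[j] = site_alts[j]
            vec[j + 1] = site_alts[j + 1]
            vec = "".join(vec)
            if vec not in known:
                i += 1
                calls.append(classify_haplotype(db, vec, sample_id=f"FRIM-{i:02d}"))
                novel_added += 1
        j += 1
    if novel_added < 6:
        raise RuntimeError("could not construct six novel haplotype vectors")

    # STR queries drawn from four northwestern source populations
    # (codes 12, 10, 13, 15), echoing the worked application
    config = SimulationConfig(seed=seed + 1)
    table, str_truth = simulate_str_dataset(config)
    rng = np.random.default_rng(seed + 2)
    source_counts = [(12, 16), (10, 12), (13, 6), (15, 6)]
    labels = [np.asarray(l) for l in (np.array(a) for a in str_truth["allele_labels"])]
    q_calls = []
    q_pops = []
    q_ids = []
    qi = 0
    for code, nq in source_counts:
        freqs = [np.asarray(p) for p in str_truth["population_freqs"][code]]
        f = config.f_region[pops.region_of(code)]
        calls_q = np.zeros((nq, config.n_loci, 2), dtype=np.int64)
        for j in range(config.n_loci):
            p = freqs[j]
            first = rng.choice(len(p), size=nq, p=p)
            second = rng.choice(len(p), size=nq, p=p)
            ibd = rng.random(nq) < f
            second[ibd] = first[ibd]
            calls_q[:, j, 0] = labels[j][first]
            calls_q[:, j, 1] = labels[j][second]
        q_calls.append(calls_q)
        for _ in range(nq):
            qi += 1
            q_ids.append(f"FRIMQ-{qi:02d}")
        q_pops.extend([code] * nq)

    query_table = STRGenotypeTable(
        q_ids,
        list(config.locus_names),
        np.concatenate(q_calls, axis=0),
        np.array(q_pops, dtype=np.int64),
        pops,
    )
    truth = dict(
        composition=dict(composition, NOVEL=6),
        source_counts=dict(source_counts),
        cpdna=cp_truth,
        reference_table=table,
        reference_truth=str_truth,
    )
    return FrimFixture(calls, query_table, truth)
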