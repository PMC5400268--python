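"""Domain types, file readers/writers and configuration shared by all stages.

The package works with three kinds of input:

* diploid STR genotype tables (GenAlEx-like delimited text: one row per
  individual, two allele columns per locus, a population code column);
* aligned chloroplast intergenic spacer sequences (FASTA, one alignment
  per spacer);
* population metadata (code, name, state, region, coordinates, sample
  sizes) joined onto genotype rows via the population code.

Allele labels are fragment sizes in base pairs and are kept as positive
integers throughout; the missing-data code (default ``"0"``) is
configurable.  Region labels are ``Western`` and ``Eastern`` (the two
genetic clusters of Peninsular Malaysia vs. Sarawak/Sabah).
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = 0
WESTERN = "Western"
EASTERN = "Eastern"
REGIONS = (WESTERN, EASTERN)

#: Malaysia bounding box (decimal degrees) used to sanity-check metadata.
_MALAYSIA_BBOX = dict(lat=(0.5, 7.5), lon=(99.0, 120.0))


class ParseError(ValueError):
    """Structured parse failure; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationTable:
    """Metadata for the sampled populations, keyed by integer code.

    ``frame`` holds one row per population with columns ``code``, ``name``,
    ``state``, ``region``, ``latitude``, ``longitude``, ``n_pop`` (haplotype
    survey sample size) and ``n_ind`` (STR database sample size).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        required = {"code", "name", "region"}
        missing = required - set(f.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        if f["code"].duplicated().any():
            dups = f.loc[f["code"].duplicated(), "code"].tolist()
            raise ValueError(f"duplicate population codes: {dups}")
        bad = set(f["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        for col, (lo, hi) in (("latitude", _MALAYSIA_BBOX["lat"]), ("longitude", _MALAYSIA_BBOX["lon"])):
            if col in f.columns:
                vals = f[col].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    raise ValueError(f"{col} outside plausible bounding box")

    @property
    def codes(self) -> list[int]:
        return [int(c) for c in self.frame["code"]]

    def region_of(self, code: int) -> str:
        row = self.frame.loc[self.frame["code"] == code]
        if row.empty:
            raise KeyError(f"unknown population code {code}")
        return str(row["region"].iloc[0])

    def region_map(self) -> dict[int, str]:
        return {int(c): str(r) for c, r in zip(self.frame["code"], self.frame["region"])}

    def name_of(self, code: int) -> str:
        row = self.frame.loc[self.frame["code"] == code]
        if row.empty:
            raise KeyError(f"unknown population code {code}")
        return str(row["name"].iloc[0])

    def codes_in_region(self, region: str) -> list[int]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [int(c) for c, r in zip(self.frame["code"], self.frame["region"]) if r == region]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# Reference sampling design: 27 natural populations across Malaysia, two
# regions separated by the South China Sea.  n_pop = haplotype survey size,
# n_ind = STR database size (totals 214 and 1032).
_REFERENCE_POPULATIONS = [
    # code, name, state, region, lat, lon, n_pop, n_ind
    (1, "Petuang", "Terengganu", WESTERN, 5.34, 102.71, 8, 16),
    (2, "Tembat", "Terengganu", WESTERN, 5.19, 102.60, 8, 47),
    (3, "Hulu Terengganu", "Terengganu", WESTERN, 4.95, 102.92, 6, 6),
    (4, "Gunung Basur", "Kelantan", WESTERN, 5.51, 101.81, 8, 35),
    (5, "Balah", "Kelantan", WESTERN, 5.25, 101.63, 8, 19),
    (6, "Gunung Stong", "Kelantan", WESTERN, 5.21, 101.95, 8, 36),
    (7, "Sungai Betis", "Kelantan", WESTERN, 4.75, 101.44, 8, 37),
    (8, "Gunung Rabong", "Kelantan", WESTERN, 4.83, 102.14, 8, 35),
    (9, "Belum", "Perak", WESTERN, 5.61, 101.66, 8, 32),
    (10, "Temenggor", "Perak", WESTERN, 5.52, 101.61, 8, 36),
    (11, "Piah", "Perak", WESTERN, 5.09, 101.33, 8, 29),
    (12, "Bintang Hijau", "Perak", WESTERN, 4.93, 100.88, 8, 44),
    (13, "Bukit Larut", "Perak", WESTERN, 4.87, 100.79, 8, 75),
    (14, "Bubu", "Perak", WESTERN, 4.66, 100.84, 8, 11),
    (15, "Bukit Kinta", "Perak", WESTERN, 4.53, 101.30, 8, 25),
    (16, "Bukit Tapah", "Perak", WESTERN, 4.40, 101.38, 8, 95),
    (17, "Ulu Jelai", "Pahang", WESTERN, 4.61, 101.90, 8, 86),
    (18, "Fraser", "Pahang", WESTERN, 3.70, 101.73, 8, 45),
    (19, "Awana", "Pahang", WESTERN, 3.39, 101.79, 8, 46),
    (20, "Gunung Bunga Buah", "Pahang", WESTERN, 3.37, 101.77, 8, 31),
    (21, "Bukit Tinggi", "Pahang", WESTERN, 3.35, 101.79, 8, 41),
    (22, "Lentang", "Pahang", WESTERN, 3.24, 102.03, 8, 10),
    (23, "Semangkok", "Selangor", WESTERN, 3.64, 101.74, 8, 52),
    (24, "Berembun", "N. Sembilan", WESTERN, 2.83, 102.05, 8, 44),
    (25, "Nanga Amang", "Sarawak", EASTERN, 1.51, 113.09, 8, 41),
    (26, "Putai", "Sarawak", EASTERN, 1.52, 114.55, 8, 29),
    (27, "Rafflesia", "Sabah", EASTERN, 5.77, 116.35, 8, 29),
]

#: The 15-locus STR panel developed for Shorea platyclados.
STR_PANEL = [
    "Spl003", "Spl529", "Spl599", "Spl600", "Spl629", "Spl667", "Spl676",
    "Spl690", "Spl763", "Spl764", "Spl834", "Spl845", "Spl855", "Spl858",
    "Spl863",
]


def malaysia_reference_populations() -> PopulationTable:
    """The 27-population, two-region Malaysian sampling design."""
    frame = pd.DataFrame(
        _REFERENCE_POPULATIONS,
        columns=["code", "name", "state", "region", "latitude", "longitude", "n_pop", "n_ind"],
    )
    return PopulationTable(frame)


# ---------------------------------------------------------------------------
# STR genotype table
# ---------------------------------------------------------------------------


@dataclass
class STRGenotypeTable:
    """Diploid STR calls for a set of individuals.

    ``calls`` is an ``(n_individuals, n_loci, 2)`` integer array of allele
    labels (fragment sizes in bp); 0 encodes a missing call.  The two slots
    per locus are an unordered pair.  ``population`` gives each individual's
    population code; regions are resolved through ``populations``.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    population: np.ndarray
    populations: PopulationTable

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.population = np.asarray(self.population, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if self.population.shape != (n,):
            raise ValueError("population vector length mismatch")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be non-negative integers (0 = missing)")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual IDs")
        known = set(self.populations.codes)
        unknown = set(self.population.tolist()) - known
        if unknown:
            raise ValueError(f"unknown population codes: {sorted(unknown)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def region(self) -> np.ndarray:
        """Per-individual region label array."""
        rmap = self.populations.region_map()
        return np.array([rmap[int(p)] for p in self.population])

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of individuals with no missing call at any locus."""
        return (self.calls > 0).all(axis=(1, 2))

    def subset(self, mask: np.ndarray) -> "STRGenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return STRGenotypeTable(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx],
            self.population[idx],
            self.populations,
        )

    def pop_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.population, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def _pool_mask(table: STRGenotypeTable, pool) -> np.ndarray:
    """Resolve a pool selector into a boolean individual mask.

    ``pool`` may be None (everyone), a region label, a population code, or an
    iterable of population codes.
    """
    if pool is None:
        return np.ones(table.n_individuals, dtype=bool)
    if isinstance(pool, str):
        if pool in REGIONS:
            return table.region() == pool
        raise ValueError(f"unknown pool selector {pool!r}")
    if isinstance(pool, (int, np.integer)):
        return table.population == int(pool)
    codes = [int(c) for c in pool]
    return np.isin(table.population, codes)


# ---------------------------------------------------------------------------
# Genotype table I/O  (GenAlEx-like dialect)
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | Path,
    populations: PopulationTable,
    missing: str = "0",
    delimiter: str = "\t",
) -> STRGenotypeTable:
    """Read a delimited genotype table.

    Layout: header row ``ID <sep> Pop <sep> L1 <sep> L1 <sep> L2 <sep> L2 ...``
    with each locus named on both of its two allele columns; one row per
    individual.  Non-numeric allele labels are rejected rather than coerced.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 4 or header[0] != "ID" or header[1] != "Pop":
            raise ParseError("header must start with 'ID', 'Pop'", line=1)
        locus_cols = header[2:]
        if len(locus_cols) % 2 != 0:
            raise ParseError(
                f"odd number of allele columns; locus {locus_cols[-1]!r} lacks its second column",
                line=1,
            )
        loci: list[str] = []
        for i in range(0, len(locus_cols), 2):
            a, b = locus_cols[i], locus_cols[i + 1]
            if a != b:
                raise ParseError(
                    f"allele columns must come in named pairs; got {a!r} followed by {b!r} "
                    f"(one allele column missing for locus {a!r}?)",
                    line=1,
                )
            if a in loci:
                raise ParseError(f"duplicate locus {a!r}", line=1)
            loci.append(a)

        individuals: list[str] = []
        pops: list[int] = []
        rows: list[list[int]] = []
        width = 2 + 2 * len(loci)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != width:
                raise ParseError(f"expected {width} fields, got {len(row)}", line=lineno)
            ind, pop_s = row[0], row[1]
            if ind in individuals:
                raise ParseError(f"duplicate individual ID {ind!r}", line=lineno)
            try:
                pop = int(pop_s)
            except ValueError:
                raise ParseError(f"non-integer population code {pop_s!r}", line=lineno) from None
            alleles: list[int] = []
            for cell in row[2:]:
                cell = cell.strip()
                if cell == missing or cell == "":
                    alleles.append(MISSING)
                    continue
                try:
                    val = int(cell)
                except ValueError:
                    raise ParseError(f"non-numeric allele label {cell!r}", line=lineno) from None
                if val <= 0:
                    raise ParseError(f"allele labels must be positive; got {val}", line=lineno)
                alleles.append(val)
            individuals.append(ind)
            pops.append(pop)
            rows.append(alleles)

    calls = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2) if rows else np.empty((0, len(loci), 2), dtype=np.int64)
    table = STRGenotypeTable(individuals, loci, calls, np.array(pops, dtype=np.int64), populations)
    logger.info("read %d individuals x %d loci from %s", table.n_individuals, table.n_loci, path)
    return table


def write_genotype_table(
    table: STRGenotypeTable,
    path: str | Path,
    missing: str = "0",
    delimiter: str = "\t",
) -> None:
    """Paired writer for :func:`read_genotype_table`; round-trips losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        header = ["ID", "Pop"]
        for locus in table.loci:
            header.extend([locus, locus])
        writer.writerow(header)
        for i, ind in enumerate(table.individuals):
            row = [ind, str(int(table.population[i]))]
            for j in range(table.n_loci):
                for k in (0, 1):
                    a = int(table.calls[i, j, k])
                    row.append(missing if a == MISSING else str(a))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Sequence alignments
# ---------------------------------------------------------------------------

_ALLOWED_CHARS = set("ACGTN-")


@dataclass
class SequenceAlignment:
    """A gapped alignment of one chloroplast intergenic spacer."""

    region_name: str
    records: dict[str, str]

    def __post_init__(self):
        if not self.records:
            raise ValueError(f"{self.region_name}: empty alignment")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            offenders = sorted(
                rid for rid, s in self.records.items() if len(s) != len(next(iter(self.records.values())))
            )
            raise ValueError(f"{self.region_name}: unequal record lengths (e.g. {offenders[:5]})")
        bad = {c for s in self.records.values() for c in s} - _ALLOWED_CHARS
        if bad:
            raise ValueError(f"{self.region_name}: unexpected characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)


def read_alignment(path: str | Path, region_name: str | None = None) -> SequenceAlignment:
    """Read a FASTA alignment; all records must share one length."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record ID {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    name = region_name if region_name is not None else path.stem
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        ref_len = len(next(iter(records.values())))
        offenders = sorted(rid for rid, s in records.items() if len(s) != ref_len)
        raise ParseError(f"{path}: records of unequal length: {offenders}")
    return SequenceAlignment(name, records)


def write_alignment(alignment: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _format_float(x: float, sig: int) -> float:
    return float(f"{x:.{sig}g}")


def _jsonable(obj, sig: int):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name), sig) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, sig) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return _format_float(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec, sig) for rec in obj.to_dict(orient="records")]
    return obj


def write_report(result, path: str | Path, format: str = "json", sig_digits: int = 6) -> None:
    """Serialize a stage output deterministically.

    JSON keeps dataclass field order; TSV writes DataFrames (or lists of
    flat dicts) with one row per record.  Floats are rounded to
    ``sig_digits`` significant digits so repeated writes are byte-identical.
    """
    path = Path(path)
    if format == "json":
        payload = _jsonable(result, sig_digits)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(result, pd.DataFrame):
            frame = result
        elif isinstance(result, list) and result and isinstance(result[0], (dict, Mapping)):
            frame = pd.DataFrame(result)
        elif dataclasses.is_dataclass(result) and not isinstance(result, type):
            frame = pd.DataFrame([_jsonable(result, sig_digits)])
        else:
            raise TypeError(f"cannot write {type(result).__name__} as TSV")
        buf = io.StringIO()
        frame = frame.copy()
        for col in frame.columns:
            if pd.api.types.is_float_dtype(frame[col]):
                frame[col] = frame[col].map(lambda x: f"{x:.{sig_digits}g}")
        frame.to_csv(buf, sep="\t", index=False, lineterminator="\n")
        with open(path, "w", newline="") as fh:
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown report format {format!r}")


def load_config(path: str | Path) -> dict:
    """Load the pipeline's structured YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
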