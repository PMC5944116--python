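"""OTU tables, rarefaction, order-level collapse and per-diet time series.

The analysis operates on order-collapsed relative abundances: sequence counts
of OTUs sharing a taxonomic order are summed per sample and divided by the
sample total, so each sample becomes a composition on the simplex over orders.
The arrangement of orders is fixed (alphabetical) and reused everywhere, so
network input/output nodes keep a stable meaning across files and runs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column headers accepted for the taxonomy column of a classic OTU table.
TAXONOMY_HEADERS = ("taxonomy", "Taxonomy", "Consensus Lineage", "ConsensusLineage")

#: Rank prefixes, most to least specific context for order extraction.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Diet label for the unfed colony; its substrate flags are all zero.
STARVED_LABEL = "starved"

SIMPLEX_ATOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """A classic OTU count table plus taxonomy and per-sample metadata.

    ``counts`` is an (n_otus, n_samples) integer matrix; ``taxonomy`` maps
    each OTU id to a semicolon-delimited lineage string; ``sample_metadata``
    maps each sample id to a ``(diet, day)`` pair.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str]
    sample_metadata: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be nonnegative")
        missing_tax = [o for o in self.otu_ids if o not in self.taxonomy]
        if missing_tax:
            raise FormatError(f"OTUs missing taxonomy: {missing_tax[:5]}")
        missing_meta = [s for s in self.sample_ids if s not in self.sample_metadata]
        if missing_meta:
            raise FormatError(
                f"samples absent from metadata: {', '.join(missing_meta[:5])}"
            )

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(
            sample_ids=list(keep),
            otu_ids=list(self.otu_ids),
            counts=self.counts[:, idx].copy(),
            taxonomy=dict(self.taxonomy),
            sample_metadata={s: self.sample_metadata[s] for s in keep},
        )


@dataclass
class RarefactionConfig:
    """Depth (sequences per sample) and seed for rarefaction."""

    depth: int = 18000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("rarefaction depth must be positive")


@dataclass
class TaxonProfile:
    """One sample's order-level relative abundances with diet/day labels."""

    sample_id: str
    diet: str
    day: int
    abundances: np.ndarray
    taxon_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.taxon_names),):
            raise ValueError("abundances length must match taxon_names")
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")
        if abs(self.abundances.sum() - 1.0) > SIMPLEX_ATOL:
            raise ValueError(
                f"abundances must sum to 1 (got {self.abundances.sum():.12f})"
            )


@dataclass
class DietSeries:
    """Time-ordered, replicate-aggregated profiles for one diet.

    ``substrate_flags`` is a 0/1 vector over the substrate name list; all
    zeros for the starved colony.
    """

    diet: str
    substrate_names: tuple[str, ...]
    substrate_flags: np.ndarray
    profiles: list[TaxonProfile]

    def __post_init__(self) -> None:
        self.substrate_flags = np.asarray(self.substrate_flags, dtype=float)
        if self.substrate_flags.shape != (len(self.substrate_names),):
            raise ValueError("substrate_flags length must match substrate_names")
        if not set(np.unique(self.substrate_flags)) <= {0.0, 1.0}:
            raise ValueError("substrate_flags must be 0/1")
        days = [p.day for p in self.profiles]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("profiles must be strictly increasing in day")

    @property
    def days(self) -> list[int]:
        return [p.day for p in self.profiles]


@dataclass
class CorePartition:
    """Core vs non-core orders by prevalence across profiles."""

    core_taxa: set[str]
    noncore_taxa: set[str]
    prevalence_threshold: float


# ---------------------------------------------------------------------------
# Reading and writing OTU tables
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_otu_table(path: str | Path, metadata_path: str | Path) -> OtuTable:
    """Read a QIIME-classic OTU table (or a comma-separated export).

    Layout: optional ``#``-prefixed comment lines, then a header whose first
    cell is ``#OTU ID`` (or ``OTU ID``), sample ids, and a final taxonomy
    column (``taxonomy`` or ``Consensus Lineage``). Metadata is a
    tab-separated file with columns ``sample_id``, ``diet``, ``day``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [ln for ln in lines if ln.strip()]
    # drop pure comment lines but keep the '#OTU ID' header
    header_idx = None
    for i, ln in enumerate(rows):
        first = ln.split("\t")[0].split(",")[0].strip()
        if first.lstrip("#").strip().lower() == "otu id":
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no '#OTU ID' header line found")
    delim = _sniff_delimiter(rows[header_idx])
    parsed = list(csv.reader(rows[header_idx:], delimiter=delim))
    header = [c.strip() for c in parsed[0]]
    if header[-1] not in TAXONOMY_HEADERS:
        raise FormatError(
            f"{path}: last column must be a taxonomy column "
            f"(one of {TAXONOMY_HEADERS}), got {header[-1]!r}"
        )
    sample_ids = header[1:-1]
    if not sample_ids:
        raise FormatError(f"{path}: table has no sample columns")
    body = [r for r in parsed[1:] if any(c.strip() for c in r)]
    if not body:
        raise FormatError(f"{path}: table has no OTU rows")
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    counts = np.empty((len(body), len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(body):
        if len(row) != len(header):
            raise FormatError(f"{path}: row {i + 2} has {len(row)} fields, "
                              f"expected {len(header)}")
        otu_ids.append(row[0].strip())
        taxonomy[row[0].strip()] = row[-1].strip()
        for j, cell in enumerate(row[1:-1]):
            val = float(cell)
            if val != int(val):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} for OTU {row[0]}"
                )
            counts[i, j] = int(val)
    metadata = read_sample_metadata(metadata_path)
    return OtuTable(sample_ids, otu_ids, counts, taxonomy, metadata)


def read_sample_metadata(path: str | Path) -> dict[str, tuple[str, int]]:
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#").strip().lower() for c in df.columns]
    required = {"sample_id", "diet", "day"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: metadata must have columns {sorted(required)}"
        )
    return {
        str(r.sample_id): (str(r.diet), int(r.day)) for r in df.itertuples()
    }


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    metadata_path: str | Path | None = None,
    taxonomy_header: str = "taxonomy",
) -> None:
    """Write a table back out in classic tab-separated layout."""
    if taxonomy_header not in TAXONOMY_HEADERS:
        raise ValueError(f"unknown taxonomy header {taxonomy_header!r}")
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids)
                 + f"\t{taxonomy_header}\n")
        for i, otu in enumerate(table.otu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{otu}\t{row}\t{table.taxonomy[otu]}\n")
    if metadata_path is not None:
        write_sample_metadata(table.sample_metadata, metadata_path)


def write_sample_metadata(
    metadata: Mapping[str, tuple[str, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdiet\tday\n")
        for sid, (diet, day) in metadata.items():
            fh.write(f"{sid}\t{diet}\t{day}\n")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, config: RarefactionConfig) -> OtuTable:
    """Subsample every sample without replacement to exactly ``config.depth``.

    Samples whose total is below the depth are dropped (and logged); a sample
    at exactly the depth is returned unchanged. Raises if no sample survives.
    """
    rng = np.random.default_rng(config.seed)
    totals = table.sample_totals()
    keep_idx = [i for i, t in enumerate(totals) if t >= config.depth]
    dropped = [s for i, s in enumerate(table.sample_ids) if i not in set(keep_idx)]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), config.depth, ", ".join(dropped),
        )
    if not keep_idx:
        raise ValueError(f"all samples are below rarefaction depth {config.depth}")
    new_counts = np.empty((len(table.otu_ids), len(keep_idx)), dtype=np.int64)
    for out_j, j in enumerate(keep_idx):
        col = table.counts[:, j]
        if totals[j] == config.depth:
            new_counts[:, out_j] = col
        else:
            new_counts[:, out_j] = rng.multivariate_hypergeometric(
                col, config.depth
            )
    kept_samples = [table.sample_ids[j] for j in keep_idx]
    return OtuTable(
        sample_ids=kept_samples,
        otu_ids=list(table.otu_ids),
        counts=new_counts,
        taxonomy=dict(table.taxonomy),
        sample_metadata={s: table.sample_metadata[s] for s in kept_samples},
    )


# ---------------------------------------------------------------------------
# Order-level collapse
# ---------------------------------------------------------------------------


def extract_order(lineage: str) -> str:
    """Return the order-level name from a semicolon-delimited lineage.

    Greengenes-style rank prefixes (``o__...``) are preferred; if the order
    field is absent or empty the OTU is binned as
    ``unclassified_<highest-resolved-rank>``. Lineages without rank prefixes
    fall back to positional rank (4th field = order).
    """
    fields = [f.strip() for f in lineage.split(";")]
    prefixed = {f[:3]: f[3:].strip() for f in fields if f[:3] in _RANK_PREFIXES}
    if prefixed:
        order = prefixed.get("o__", "")
        if order:
            return order
        highest = ""
        for pref in ("c__", "p__", "k__"):
            if prefixed.get(pref):
                highest = prefixed[pref]
                break
        return f"unclassified_{highest or 'root'}"
    # positional: kingdom;phylum;class;order;...
    if len(fields) >= 4 and fields[3]:
        return fields[3]
    resolved = [f for f in fields if f]
    return f"unclassified_{resolved[-1] if resolved else 'root'}"


def collapse_to_orders(table: OtuTable) -> list[TaxonProfile]:
    """Sum OTU counts per taxonomic order and normalise per sample.

    Orders are arranged alphabetically; that fixed arrangement is shared by
    every returned profile so downstream vectors are comparable.
    """
    orders = [extract_order(table.taxonomy[o]) for o in table.otu_ids]
    unresolved = sorted({o for o in orders if o.startswith("unclassified_")})
    if unresolved:
        logger.info("collapse_to_orders: unresolved order bins: %s",
                    ", ".join(unresolved))
    order_names = tuple(sorted(set(orders)))
    order_index = {name: k for k, name in enumerate(order_names)}
    collapsed = np.zeros((len(order_names), len(table.sample_ids)))
    for i, order in enumerate(orders):
        collapsed[order_index[order]] += table.counts[i]
    totals = collapsed.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {bad}")
    rel = collapsed / totals
    profiles = []
    for j, sid in enumerate(table.sample_ids):
        diet, day = table.sample_metadata[sid]
        profiles.append(TaxonProfile(sid, diet, day, rel[:, j], order_names))
    return profiles


# ---------------------------------------------------------------------------
# Core / non-core partition
# ---------------------------------------------------------------------------


def partition_core(
    profiles: Sequence[TaxonProfile], prevalence_threshold: float = 1.0
) -> CorePartition:
    """An order is core iff nonzero in >= threshold fraction of profiles."""
    if not profiles:
        raise ValueError("partition_core requires at least one profile")
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence_threshold must be in (0, 1]")
    names = profiles[0].taxon_names
    present = np.stack([p.abundances > 0 for p in profiles])
    prevalence = present.mean(axis=0)
    core = {n for n, f in zip(names, prevalence) if f >= prevalence_threshold}
    return CorePartition(
        core_taxa=core,
        noncore_taxa=set(names) - core,
        prevalence_threshold=prevalence_threshold,
    )


# ---------------------------------------------------------------------------
# Per-diet series assembly
# ---------------------------------------------------------------------------


def _mean_profile(
    profiles: Sequence[TaxonProfile], sample_id: str, diet: str, day: int
) -> TaxonProfile:
    mat = np.stack([p.abundances for p in profiles])
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    return TaxonProfile(sample_id, diet, day, mean, profiles[0].taxon_names)


def substrate_flags_for(diet: str, substrate_names: Sequence[str]) -> np.ndarray:
    """One-hot flags for the diet's own substrate; all zero when starved."""
    flags = np.zeros(len(substrate_names))
    if diet == STARVED_LABEL:
        return flags
    if diet not in substrate_names:
        raise ValueError(
            f"diet {diet!r} is not a known substrate {list(substrate_names)} "
            f"and is not {STARVED_LABEL!r}"
        )
    flags[list(substrate_names).index(diet)] = 1.0
    return flags


def build_diet_series(
    profiles: Sequence[TaxonProfile],
    substrate_names: Sequence[str],
    aggregation: str = "mean",
) -> list[DietSeries]:
    """Assemble per-diet time series from labelled profiles.

    All day-0 profiles (whatever their diet label) are pooled and their
    renormalised mean is prepended as every series' first row: every colony
    derives from the same starting stock. With ``aggregation='mean'``
    replicates at each (diet, day) are averaged then renormalised; with
    ``'per_replicate'`` each replicate rank yields its own series (days where
    that rank is missing fall back to the day mean).
    """
    if aggregation not in ("mean", "per_replicate"):
        raise ValueError("aggregation must be 'mean' or 'per_replicate'")
    day0 = [p for p in profiles if p.day == 0]
    if not day0:
        raise ValueError("no day-0 profiles; every series needs a first row")
    day0_profile = _mean_profile(day0, "day0_pooled", "day0", 0)

    by_diet: dict[str, dict[int, list[TaxonProfile]]] = {}
    for p in profiles:
        if p.day == 0:
            continue
        by_diet.setdefault(p.diet, {}).setdefault(p.day, []).append(p)

    series: list[DietSeries] = []
    sub_names = tuple(substrate_names)
    for diet in sorted(by_diet):
        flags = substrate_flags_for(diet, sub_names)
        days = sorted(by_diet[diet])
        if len(days) < 1:
            raise ValueError(f"diet {diet!r} has fewer than 2 time points")
        if aggregation == "mean":
            prof_list = [
                TaxonProfile(day0_profile.sample_id, diet, 0,
                             day0_profile.abundances, day0_profile.taxon_names)
            ]
            for day in days:
                reps = sorted(by_diet[diet][day], key=lambda p: p.sample_id)
                prof_list.append(_mean_profile(reps, f"{diet}_d{day}", diet, day))
            series.append(DietSeries(diet, sub_names, flags, prof_list))
        else:
            n_rep = max(len(v) for v in by_diet[diet].values())
            for r in range(n_rep):
                prof_list = [
                    TaxonProfile(day0_profile.sample_id, diet, 0,
                                 day0_profile.abundances,
                                 day0_profile.taxon_names)
                ]
                for day in days:
                    reps = sorted(by_diet[diet][day], key=lambda p: p.sample_id)
                    if r < len(reps):
                        p = reps[r]
                        prof_list.append(
                            TaxonProfile(p.sample_id, diet, day,
                                         p.abundances, p.taxon_names)
                        )
                    else:
                        prof_list.append(
                            _mean_profile(reps, f"{diet}_d{day}", diet, day)
                        )
                series.append(DietSeries(diet, sub_names, flags, prof_list))
    for s in series:
        if len(s.profiles) < 2:
            raise ValueError(
                f"diet {s.diet!r} has fewer than 2 time points; "
                "no training pair possible"
            )
    return series


# ---------------------------------------------------------------------------
# Per-diet series files
# ---------------------------------------------------------------------------


def write_diet_series_csv(series: DietSeries, path: str | Path) -> None:
    """One comma-separated file per diet: taxon columns then substrate flags.

    Sampling days are recorded in a comment line; rows are time points in
    day order.
    """
    with open(path, "w") as fh:
        fh.write(f"# diet: {series.diet}\n")
        fh.write(f"# days: {','.join(str(d) for d in series.days)}\n")
        fh.write(f"# substrates: {','.join(series.substrate_names)}\n")
        names = list(series.profiles[0].taxon_names) + list(series.substrate_names)
        fh.write(",".join(names) + "\n")
        for p in series.profiles:
            vals = list(p.abundances) + list(series.substrate_flags)
            fh.write(",".join(f"{v:.10g}" for v in vals) + "\n")


def read_diet_series_csv(path: str | Path) -> DietSeries:
    """Read a per-diet series file written by :func:`write_diet_series_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            key, _, val = ln.lstrip("#").partition(":")
            meta[key.strip()] = val.strip()
        elif ln.strip():
            rows.append(ln)
    for key in ("diet", "days", "substrates"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}:' comment line")
    diet = meta["diet"]
    days = [int(d) for d in meta["days"].split(",")]
    substrate_names = tuple(s.strip() for s in meta["substrates"].split(","))
    header = [c.strip() for c in rows[0].split(",")]
    n_sub = len(substrate_names)
    taxon_names = tuple(header[:-n_sub])
    if tuple(header[-n_sub:]) != substrate_names:
        raise FormatError(f"{path}: trailing columns do not match substrates")
    data = np.array([[float(c) for c in r.split(",")] for r in rows[1:]])
    if data.shape[0] != len(days):
        raise FormatError(f"{path}: {data.shape[0]} rows but {len(days)} days")
    flags = data[0, -n_sub:]
    profiles = [
        TaxonProfile(f"{diet}_d{day}", diet, day,
                     data[i, : -n_sub] / data[i, : -n_sub].sum(), taxon_names)
        for i, day in enumerate(days)
    ]
    return DietSeries(diet, substrate_names, flags, profiles)
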