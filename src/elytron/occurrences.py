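"""Fossil occurrence records and range-through diversity curves.

An occurrence database is a CSV with one row per taxon giving its rank
(species / genus / family), its curation status (natural taxa are based
on diagnosable whole-body material; formal taxa are form categories
erected on isolated elytra), its parent genus/family, and its first and
last appearance as stage names.  Diversity is computed with the
range-through method: a taxon counts in every bin between and including
its first and last appearance bins.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from elytron.timebins import TimeBinScheme, UnknownStageError

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family")
STATUSES = ("natural", "formal")
TAXON_SETS = ("natural", "formal", "mixed")
CURATION_FLAGS = ("illegitimate", "questionable", "synonym")

REQUIRED_COLUMNS = (
    "taxon_name",
    "rank",
    "status",
    "family",
    "genus",
    "first_stage",
    "last_stage",
    "flags",
)


class OccurrenceFormatError(ValueError):
    """The file as a whole is malformed (e.g. a required column is absent)."""


class OccurrenceValidationError(ValueError):
    """One or more rows failed validation; the offending rows are listed."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {r}: {msg}" for r, msg in row_errors)
        super().__init__(f"{len(row_errors)} invalid occurrence row(s): {lines}")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One taxon's rank, status and stratigraphic range in bin indices."""

    taxon_name: str
    rank: str
    status: str
    first_bin: int
    last_bin: int
    parent_genus: str = ""
    parent_family: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.first_bin > self.last_bin:
            raise ValueError(
                f"{self.taxon_name!r}: first_bin {self.first_bin} > "
                f"last_bin {self.last_bin}"
            )


@dataclass
class DiversityCurve:
    """Range-through richness per time-bin for one rank and taxon set."""

    rank: str
    taxon_set: str
    counts: np.ndarray  # one non-negative integer per bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("diversity counts must be non-negative")


def load_occurrences(path, scheme: TimeBinScheme) -> list[OccurrenceRecord]:
    """Read an occurrence CSV, resolving stage names against ``scheme``.

    Rows with unresolvable stages or inverted ranges are collected and
    raised together in an :class:`OccurrenceValidationError` naming each
    row, never silently dropped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise OccurrenceFormatError(
            f"{path}: missing required column(s): {', '.join(missing_cols)}"
        )

    records: list[OccurrenceRecord] = []
    row_errors: list[tuple[int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            first = scheme.resolve_stage(row.first_stage)
        except UnknownStageError:
            row_errors.append((pos, f"unknown first_stage {row.first_stage!r}"))
            continue
        try:
            last = scheme.resolve_stage(row.last_stage)
        except UnknownStageError:
            row_errors.append((pos, f"unknown last_stage {row.last_stage!r}"))
            continue
        if first.index > last.index:
            row_errors.append(
                (pos, f"first_stage {row.first_stage!r} is younger than "
                      f"last_stage {row.last_stage!r}")
            )
            continue
        flags = frozenset(f.strip() for f in row.flags.split(";") if f.strip())
        bad_flags = flags - set(CURATION_FLAGS)
        if bad_flags:
            row_errors.append((pos, f"unknown flag(s) {sorted(bad_flags)}"))
            continue
        try:
            records.append(
                OccurrenceRecord(
                    taxon_name=row.taxon_name.strip(),
                    rank=row.rank.strip().lower(),
                    status=row.status.strip().lower(),
                    first_bin=first.index,
                    last_bin=last.index,
                    parent_genus=row.genus.strip(),
                    parent_family=row.family.strip(),
                    flags=flags,
                )
            )
        except ValueError as exc:
            row_errors.append((pos, str(exc)))
    if row_errors:
        raise OccurrenceValidationError(row_errors)
    return records


def apply_curation_filter(
    records: list[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """Drop records flagged illegitimate, questionable or synonym.

    Returns the retained records and a per-flag exclusion count (a
    record carrying two flags counts under both).
    """
    kept = [r for r in records if not r.flags]
    counts: Counter[str] = Counter()
    for r in records:
        for f in r.flags:
            counts[f] += 1
    if records and not kept:
        logger.warning("curation filter removed every record (%d)", len(records))
    report = {f: counts.get(f, 0) for f in CURATION_FLAGS}
    logger.info(
        "curation filter: kept %d of %d records (%s)", len(kept), len(records), report
    )
    return kept, report


def _ranges_at_rank(
    records: list[OccurrenceRecord], rank: str
) -> dict[str, tuple[int, int]]:
    """Name -> (first_bin, last_bin) at the requested rank.

    Genus/family ranges are the union of directly recorded ranges at
    that rank and the ranges of contained lower-rank records, whichever
    is wider.
    """
    ranges: dict[str, tuple[int, int]] = {}

    def extend(name: str, first: int, last: int) -> None:
        if not name:
            return
        if name in ranges:
            lo, hi = ranges[name]
            ranges[name] = (min(lo, first), max(hi, last))
        else:
            ranges[name] = (first, last)

    for r in records:
        if rank == "species":
            if r.rank == "species":
                extend(r.taxon_name, r.first_bin, r.last_bin)
        elif rank == "genus":
            if r.rank == "genus":
                extend(r.taxon_name, r.first_bin, r.last_bin)
            elif r.rank == "species":
                extend(r.parent_genus, r.first_bin, r.last_bin)
        elif rank == "family":
            if r.rank == "family":
                extend(r.taxon_name, r.first_bin, r.last_bin)
            else:
                extend(r.parent_family, r.first_bin, r.last_bin)
    return ranges


def range_through_counts(
    records: list[OccurrenceRecord],
    rank: str,
    taxon_set: str,
    scheme: TimeBinScheme,
) -> DiversityCurve:
    """Range-through richness per bin at ``rank`` for ``taxon_set``.

    ``mixed`` pools natural and formal records, deduplicating taxa by
    exact name (a name present in both sets counts once, with the union
    of its ranges).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if taxon_set not in TAXON_SETS:
        raise ValueError(
            f"unknown taxon_set {taxon_set!r}; expected one of {TAXON_SETS}"
        )
    if taxon_set == "mixed":
        subset = records
    else:
        subset = [r for r in records if r.status == taxon_set]
    ranges = _ranges_at_rank(subset, rank)
    counts = np.zeros(len(scheme), dtype=int)
    for first, last in ranges.values():
        counts[first : last + 1] += 1
    return DiversityCurve(rank=rank, taxon_set=taxon_set, counts=counts)


def distinct_taxa(
    records: list[OccurrenceRecord], rank: str, taxon_set: str
) -> set[str]:
    """Distinct taxon names at a rank within a taxon set (name-keyed)."""
    if taxon_set == "mixed":
        subset = records
    else:
        subset = [r for r in records if r.status == taxon_set]
    return set(_ranges_at_rank(subset, rank))


def diversity_table(
    curves: list[DiversityCurve], scheme: TimeBinScheme
) -> pd.DataFrame:
    """Tidy table: bin_name, bin_index, rank, taxon_set, count."""
    rows = []
    for curve in curves:
        for b, count in zip(scheme.bins, curve.counts):
            rows.append(
                {
                    "bin_name": b.name,
                    "bin_index": b.index,
                    "rank": curve.rank,
                    "taxon_set": curve.taxon_set,
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows)
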