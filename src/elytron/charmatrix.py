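"""Discrete morphological character matrices with missing data.

Cells hold a single integer state, a set of states (polymorphism), or
one of two non-data markers: ``MISSING`` ("?", state unknown) and
``INAPPLICABLE`` ("-", character not applicable to the taxon).  The two
markers are kept distinct through I/O; the distance metrics treat both
as incomparable.

Matrices are read and written in two dialects: a NEXUS subset
(DATA/CHARACTERS block with a MATRIX, "(..)"/"{..}" polymorphism, and an
optional ASSUMPTIONS block carrying ordering flags) and a plain CSV
table with one taxon per row.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from elytron.timebins import TimeBinScheme

logger = logging.getLogger(__name__)

MISSING = "?"
INAPPLICABLE = "-"

Cell = object  # int | frozenset[int] | MISSING | INAPPLICABLE


class MatrixFormatError(ValueError):
    """Structurally malformed matrix file (ragged rows, bad tokens...)."""


class MatrixValidationError(ValueError):
    """Well-formed file with invalid content (e.g. state > max_state)."""


@dataclass(frozen=True)
class CharacterDefinition:
    index: int
    ordered: bool = False
    max_state: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.max_state < 1:
            raise ValueError(
                f"character {self.index}: max_state must be >= 1 "
                f"(got {self.max_state})"
            )


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of discrete states.

    ``bin_label`` maps taxon name to a time-bin index and ``group_label``
    to an arbitrary grouping code (e.g. an epoch); both are optional at
    construction but every taxon entering a disparity computation must
    carry a bin label.
    """

    taxa: list[str]
    characters: list[CharacterDefinition]
    states: list[list[Cell]]
    bin_label: dict[str, int] = field(default_factory=dict)
    group_label: dict[str, str] = field(default_factory=dict)
    level: str = "species"

    def __post_init__(self) -> None:
        n, c = len(self.taxa), len(self.characters)
        if len(self.states) != n:
            raise MatrixValidationError(
                f"{len(self.states)} state rows for {n} taxa"
            )
        for i, row in enumerate(self.states):
            if len(row) != c:
                raise MatrixFormatError(
                    f"row {i + 1} ({self.taxa[i]!r}) has {len(row)} cells, "
                    f"expected {c}"
                )
        if len(set(self.taxa)) != n:
            raise MatrixValidationError("duplicate taxon labels")
        for i, row in enumerate(self.states):
            for k, cell in enumerate(row):
                for s in _cell_states(cell):
                    if s < 0 or s > self.characters[k].max_state:
                        raise MatrixValidationError(
                            f"taxon {self.taxa[i]!r}, character {k + 1}: state "
                            f"{s} exceeds max_state {self.characters[k].max_state}"
                        )
        empty = [
            t
            for t, row in zip(self.taxa, self.states)
            if all(cell in (MISSING, INAPPLICABLE) for cell in row)
        ]
        if empty:
            logger.warning("taxa with no scored characters: %s", empty)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def cell(self, taxon: str, char_index: int) -> Cell:
        return self.states[self.taxa.index(taxon)][char_index]

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in keep]
        return replace(
            self,
            taxa=list(keep),
            states=[self.states[i] for i in idx],
            bin_label={t: b for t, b in self.bin_label.items() if t in keep},
            group_label={t: g for t, g in self.group_label.items() if t in keep},
        )


def _cell_states(cell: Cell) -> tuple[int, ...]:
    if cell == MISSING or cell == INAPPLICABLE:
        return ()
    if isinstance(cell, frozenset):
        return tuple(sorted(cell))
    return (int(cell),)


def _parse_state_string(text: str, row_label: str) -> list[Cell]:
    """Tokenize one MATRIX row body: digits, '?', '-', '(..)' and '{..}'."""
    cells: list[Cell] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == MISSING:
            cells.append(MISSING)
            i += 1
        elif ch == INAPPLICABLE:
            cells.append(INAPPLICABLE)
            i += 1
        elif ch.isdigit():
            cells.append(int(ch))
            i += 1
        elif ch in "({":
            close = ")" if ch == "(" else "}"
            end = text.find(close, i)
            if end < 0:
                raise MatrixFormatError(
                    f"{row_label}: unterminated polymorphism {text[i:]!r}"
                )
            inner = [c for c in text[i + 1 : end] if not c.isspace() and c != ","]
            if not all(c.isdigit() for c in inner) or not inner:
                raise MatrixFormatError(
                    f"{row_label}: bad polymorphism token {text[i:end + 1]!r}"
                )
            states = frozenset(int(c) for c in inner)
            cells.append(next(iter(states)) if len(states) == 1 else states)
            i = end + 1
        else:
            raise MatrixFormatError(f"{row_label}: unexpected character {ch!r}")
    return cells


def _format_cell(cell: Cell) -> str:
    if cell == MISSING or cell == INAPPLICABLE:
        return cell
    if isinstance(cell, frozenset):
        return "(" + "".join(str(s) for s in sorted(cell)) + ")"
    return str(cell)


def _infer_characters(
    states: list[list[Cell]], n_char: int, ordered: set[int]
) -> list[CharacterDefinition]:
    """Character definitions with max_state = observed maximum (min 1)."""
    defs = []
    for k in range(n_char):
        observed = [s for row in states for s in _cell_states(row[k])]
        defs.append(
            CharacterDefinition(
                index=k,
                ordered=k in ordered,
                max_state=max(observed, default=1) or 1,
            )
        )
    return defs


_NEXUS_RANGE = re.compile(r"(\d+)(?:\s*-\s*(\d+))?")


def _parse_assumptions_ordered(block: str) -> set[int]:
    """0-based indices of characters declared ``ord`` in a TYPESET line."""
    ordered: set[int] = set()
    m = re.search(r"TYPESET[^=]*=(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not m:
        return ordered
    for part in m.group(1).split(","):
        if ":" not in part:
            continue
        kind, chars = part.split(":", 1)
        if kind.strip().lower() not in ("ord", "ordered"):
            continue
        for rng in _NEXUS_RANGE.finditer(chars):
            lo = int(rng.group(1))
            hi = int(rng.group(2) or lo)
            ordered.update(range(lo - 1, hi))
    return ordered


def _dedupe_taxa(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate taxon label %r renamed to %r", name, new)
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


def _read_nexus(path) -> tuple[list[str], list[list[Cell]], set[int]]:
    text = open(path, encoding="utf-8").read()
    stripped = re.sub(r"\[[^\]]*\]", "", text)  # NEXUS comments
    m = re.search(r"MATRIX(.*?);", stripped, re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixFormatError(f"{path}: no MATRIX block found")
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    for lineno, line in enumerate(m.group(1).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            # quoted label: taken literally ('' is an escaped quote)
            i = 1
            while True:
                end = line.index("'", i)
                if line[end : end + 2] == "''":
                    i = end + 2
                    continue
                break
            name = line[1:end].replace("''", "'")
            body = line[end + 1 :]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise MatrixFormatError(
                    f"{path} matrix line {lineno}: expected 'taxon states'"
                )
            name, body = parts
            name = name.replace("_", " ")
        taxa.append(name.strip())
        rows.append(_parse_state_string(body, f"{path} matrix line {lineno}"))
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        bad = next(i + 1 for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise MatrixFormatError(
            f"{path}: ragged MATRIX rows (row {bad}); lengths seen: {sorted(lengths)}"
        )
    dims = re.search(r"NCHAR\s*=\s*(\d+)", stripped, re.IGNORECASE)
    if dims and rows and int(dims.group(1)) != len(rows[0]):
        raise MatrixFormatError(
            f"{path}: NCHAR={dims.group(1)} but rows have {len(rows[0])} cells"
        )
    ordered: set[int] = set()
    am = re.search(
        r"BEGIN\s+ASSUMPTIONS\s*;(.*?)END\s*;", stripped, re.IGNORECASE | re.DOTALL
    )
    if am:
        ordered = _parse_assumptions_ordered(am.group(1))
    return taxa, rows, ordered


def _read_table(path) -> tuple[list[str], list[list[Cell]]]:
    taxa: list[str] = []
    rows: list[list[Cell]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise MatrixFormatError(f"{path}: empty table")
        width = len(header) - 1
        for lineno, parts in enumerate(reader, start=2):
            if not parts:
                continue
            if len(parts) - 1 != width:
                raise MatrixFormatError(
                    f"{path} row {lineno}: {len(parts) - 1} cells, expected {width}"
                )
            taxa.append(parts[0])
            rows.append(
                [
                    _parse_state_string(tok.strip(), f"{path} row {lineno}")[0]
                    if tok.strip()
                    else MISSING
                    for tok in parts[1:]
                ]
            )
    return taxa, rows


def read_character_matrix(path, dialect: str = "nexus") -> CharacterMatrix:
    """Read a matrix in the ``nexus`` or ``table`` dialect.

    max_state per character is inferred as the largest observed state;
    ordering flags come from a NEXUS ASSUMPTIONS TYPESET when present
    (all characters unordered otherwise).
    """
    if dialect == "nexus":
        taxa, rows, ordered = _read_nexus(path)
    elif dialect == "table":
        taxa, rows = _read_table(path)
        ordered = set()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    taxa = _dedupe_taxa(taxa)
    n_char = len(rows[0]) if rows else 0
    chars = _infer_characters(rows, n_char, ordered)
    return CharacterMatrix(taxa=taxa, characters=chars, states=rows)


def write_character_matrix(m: CharacterMatrix, path, dialect: str = "nexus") -> None:
    if dialect == "nexus":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(
                f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};\n"
                "  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS=\"0123456789\";\n"
                "  MATRIX\n"
            )
            for taxon, row in zip(m.taxa, m.states):
                # quote labels with non-alphanumerics so underscores survive
                # the round trip (bare underscores mean spaces in NEXUS)
                if re.search(r"[^A-Za-z0-9]", taxon):
                    label = "'" + taxon.replace("'", "''") + "'"
                else:
                    label = taxon
                fh.write(f"    {label}  {''.join(_format_cell(c) for c in row)}\n")
            fh.write("  ;\nEND;\n")
            ordered = [c.index + 1 for c in m.characters if c.ordered]
            if ordered:
                spans = ",".join(str(i) for i in ordered)
                fh.write(
                    "\nBEGIN ASSUMPTIONS;\n"
                    f"  TYPESET * UNTITLED = ord: {spans};\n"
                    "END;\n"
                )
    elif dialect == "table":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["taxon"] + [f"char_{c.index + 1}" for c in m.characters])
            for taxon, row in zip(m.taxa, m.states):
                writer.writerow([taxon] + [_format_cell(c) for c in row])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_taxon_metadata(
    m: CharacterMatrix, path, scheme: TimeBinScheme
) -> CharacterMatrix:
    """Attach bin and group labels from a sidecar CSV.

    The sidecar has columns taxon_name, bin_name and optionally group;
    bin_name must name a bin of ``scheme``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("taxon_name", "bin_name"):
        if col not in df.columns:
            raise MatrixFormatError(f"{path}: missing column {col!r}")
    bin_label = dict(m.bin_label)
    group_label = dict(m.group_label)
    for row in df.itertuples(index=False):
        b = scheme.bin_by_name(row.bin_name)
        bin_label[row.taxon_name] = b.index
        if hasattr(row, "group"):
            group_label[row.taxon_name] = row.group
    return replace(m, bin_label=bin_label, group_label=group_label)


@dataclass
class CompletenessSummary:
    per_taxon: pd.Series  # missing fraction per taxon
    per_character: pd.Series  # missing fraction per character
    overall: float


def completeness_summary(m: CharacterMatrix) -> CompletenessSummary:
    """Missing-data fractions (MISSING and INAPPLICABLE both count)."""
    mask = np.array(
        [[cell in (MISSING, INAPPLICABLE) for cell in row] for row in m.states],
        dtype=bool,
    )
    return CompletenessSummary(
        per_taxon=pd.Series(mask.mean(axis=1), index=m.taxa),
        per_character=pd.Series(
            mask.mean(axis=0), index=[f"char_{c.index + 1}" for c in m.characters]
        ),
        overall=float(mask.mean()) if mask.size else 0.0,
    )
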