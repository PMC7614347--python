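"""Discrete morphological character matrices: types, NEXUS/TNT I/O, summaries.

A matrix is a taxa x characters grid of cells. Each cell is either an
observed set of states (a singleton for ordinary codings, larger for
polymorphic/uncertain codings), a missing entry (``?``), or an
inapplicable entry (``-``, as produced by reductive coding of
hierarchically dependent characters). Taxa carry an extant/fossil flag,
read from a two-column sidecar table since neither NEXUS nor TNT has a
standard slot for it.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "CellKind",
    "CharacterCell",
    "TaxonRecord",
    "CharacterMeta",
    "CharacterMatrix",
    "MatrixFormatError",
    "MatrixSummary",
    "read_matrix",
    "write_matrix",
    "matrix_summary",
]

# TNT-style state alphabet: digits then uppercase letters for >= 10 states.
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class MatrixFormatError(ValueError):
    """Malformed matrix file; message carries line/position context."""


class CellKind(str, Enum):
    OBSERVED = "observed"
    MISSING = "missing"
    INAPPLICABLE = "inapplicable"


@dataclass(frozen=True)
class CharacterCell:
    """One scoring of one character in one taxon."""

    states: frozenset
    kind: CellKind = CellKind.OBSERVED

    def __post_init__(self):
        if self.kind is CellKind.OBSERVED:
            if not self.states:
                raise ValueError("observed cell needs at least one state")
        elif self.states:
            raise ValueError(f"{self.kind.value} cell must have empty state set")

    @staticmethod
    def observed(states: Iterable[int]) -> "CharacterCell":
        return CharacterCell(frozenset(int(s) for s in states), CellKind.OBSERVED)

    @staticmethod
    def missing() -> "CharacterCell":
        return CharacterCell(frozenset(), CellKind.MISSING)

    @staticmethod
    def inapplicable() -> "CharacterCell":
        return CharacterCell(frozenset(), CellKind.INAPPLICABLE)

    @property
    def is_observed(self) -> bool:
        return self.kind is CellKind.OBSERVED


@dataclass
class TaxonRecord:
    name: str
    extant: bool = True


@dataclass
class CharacterMeta:
    index: int
    n_states: int = 2
    ordered: bool = False
    label: Optional[str] = None


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of :class:`CharacterCell` values."""

    taxa: list
    characters: list
    cells: list  # cells[i][j]: taxon i, character j

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate taxon name(s): {dup}")
        if len(self.cells) != len(self.taxa):
            raise ValueError(
                f"{len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        for i, row in enumerate(self.cells):
            if len(row) != len(self.characters):
                raise ValueError(
                    f"row {self.taxa[i].name!r}: {len(row)} cells for "
                    f"{len(self.characters)} characters"
                )
        for j, meta in enumerate(self.characters):
            max_obs = max(
                (max(row[j].states) for row in self.cells if row[j].states),
                default=-1,
            )
            if meta.n_states < max_obs + 1:
                raise ValueError(
                    f"character {j}: declared {meta.n_states} states but "
                    f"observed state {max_obs}"
                )
            if meta.n_states < 2:
                meta.n_states = 2

    # -- accessors -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def taxon_names(self) -> list:
        return [t.name for t in self.taxa]

    def taxon_index(self, name: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.name == name:
                return i
        raise KeyError(name)

    def row(self, name: str) -> list:
        return self.cells[self.taxon_index(name)]

    def cell(self, taxon: str, char: int) -> CharacterCell:
        return self.cells[self.taxon_index(taxon)][char]

    def subset_taxa(self, names: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_index(n) for n in names]
        return CharacterMatrix(
            taxa=[self.taxa[i] for i in idx],
            characters=[CharacterMeta(**vars(c)) for c in self.characters],
            cells=[list(self.cells[i]) for i in idx],
        )

    def subset_characters(self, char_idx: Sequence[int]) -> "CharacterMatrix":
        metas = [
            CharacterMeta(j, self.characters[c].n_states,
                          self.characters[c].ordered, self.characters[c].label)
            for j, c in enumerate(char_idx)
        ]
        return CharacterMatrix(
            taxa=[TaxonRecord(t.name, t.extant) for t in self.taxa],
            characters=metas,
            cells=[[row[c] for c in char_idx] for row in self.cells],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        # declared state counts are derived metadata (NEXUS/TNT carry a
        # global symbol list, not per-character counts), so equality is
        # taxon-, flag- and cell-level
        return (
            [(t.name, t.extant) for t in self.taxa]
            == [(t.name, t.extant) for t in other.taxa]
            and [c.ordered for c in self.characters]
            == [c.ordered for c in other.characters]
            and self.cells == other.cells
        )


# ---------------------------------------------------------------------------
# symbols


def state_symbol(state: int) -> str:
    if not 0 <= state < len(_SYMBOLS):
        raise ValueError(f"state {state} outside symbol alphabet")
    return _SYMBOLS[state]


def symbol_state(symbol: str) -> int:
    try:
        return _SYMBOLS.index(symbol.upper())
    except ValueError:
        raise MatrixFormatError(f"unknown state symbol {symbol!r}") from None


# ---------------------------------------------------------------------------
# reading


def read_matrix(path, dialect: str = "auto",
                taxon_table: Optional[str] = None) -> CharacterMatrix:
    """Read a NEXUS or TNT morphological matrix.

    ``?`` maps to missing, ``-`` to inapplicable, brace/bracket groups to
    multi-state cells. Extant/fossil flags come from ``taxon_table`` (TSV:
    name, ``extant``/``fossil``) or a ``<path>.taxa.tsv`` sibling; absent
    either, every taxon is flagged extant.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        dialect = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "tnt"
    if dialect == "nexus":
        matrix = _read_nexus(text, str(path))
    elif dialect == "tnt":
        matrix = _read_tnt(text, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    sidecar = Path(taxon_table) if taxon_table else path.with_suffix(path.suffix + ".taxa.tsv")
    if sidecar.exists():
        _apply_taxon_table(matrix, sidecar)
    return matrix


def _read_nexus(text: str, source: str) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise MatrixFormatError(f"{source}: {exc}") from exc
    taxa, rows = [], []
    n_char = None
    for taxon in dmat:
        seq = dmat[taxon]
        row = []
        for s in seq:
            if s.symbol == "?":
                row.append(CharacterCell.missing())
            elif s.symbol == "-":
                row.append(CharacterCell.inapplicable())
            else:
                states = frozenset(
                    symbol_state(fs.symbol)
                    for fs in s.fundamental_states
                    if fs.symbol not in ("-", "?")
                )
                if not states:
                    row.append(CharacterCell.missing())
                else:
                    row.append(CharacterCell(states, CellKind.OBSERVED))
        if n_char is None:
            n_char = len(row)
        elif len(row) != n_char:
            raise MatrixFormatError(
                f"{source}: taxon {taxon.label!r} has {len(row)} cells, "
                f"expected {n_char}"
            )
        taxa.append(TaxonRecord(_norm_name(taxon.label)))
        rows.append(row)
    return _assemble(taxa, rows, source)


_TNT_CELL = re.compile(r"\[([^\]]*)\]|\{([^}]*)\}|(\S)")


def _read_tnt(text: str, source: str) -> CharacterMatrix:
    lines = text.splitlines()
    it = iter(enumerate(lines, start=1))
    header = None
    for lineno, line in it:
        stripped = line.split("'")[0].strip()
        if stripped.lower().startswith("xread"):
            header = stripped[len("xread"):].strip()
            break
    if header is None:
        raise MatrixFormatError(f"{source}: no xread block found")
    # the nchar/ntax counts may trail 'xread' or sit on following lines
    tokens = header.split()
    while len(tokens) < 2:
        try:
            lineno, line = next(it)
        except StopIteration:
            raise MatrixFormatError(f"{source}: xread dimensions missing")
        tokens += line.split("'")[0].split()
    try:
        n_char, n_tax = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise MatrixFormatError(
            f"{source}:{lineno}: bad xread dimensions {tokens[:2]}"
        ) from None

    order: list = []
    data: dict = {}
    for lineno, line in it:
        stripped = line.strip()
        if not stripped or stripped.startswith("'"):
            continue
        if stripped.startswith(";"):
            break
        if stripped.startswith("&"):  # interleave marker
            continue
        parts = stripped.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(
                f"{source}:{lineno}: expected 'taxon states', got {stripped!r}"
            )
        name, statestr = _norm_name(parts[0]), parts[1].replace(" ", "")
        if name not in data:
            order.append(name)
            data[name] = []
        pos = 0
        for m in _TNT_CELL.finditer(statestr):
            grp = m.group(1) if m.group(1) is not None else m.group(2)
            if grp is not None:
                data[name].append(
                    CharacterCell.observed(symbol_state(c) for c in grp)
                )
            else:
                ch = m.group(3)
                if ch == "?":
                    data[name].append(CharacterCell.missing())
                elif ch == "-":
                    data[name].append(CharacterCell.inapplicable())
                else:
                    data[name].append(
                        CharacterCell.observed([symbol_state(ch)])
                    )
            pos += 1

    if len(order) != n_tax:
        raise MatrixFormatError(
            f"{source}: declared {n_tax} taxa, found {len(order)}"
        )
    rows = []
    for name in order:
        if len(data[name]) != n_char:
            raise MatrixFormatError(
                f"{source}: taxon {name!r} has {len(data[name])} cells, "
                f"declared nchar={n_char}"
            )
        rows.append(data[name])
    return _assemble([TaxonRecord(n) for n in order], rows, source)


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip())


def _assemble(taxa, rows, source) -> CharacterMatrix:
    names = [t.name for t in taxa]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise MatrixFormatError(f"{source}: duplicate taxon name(s) {dup}")
    n_char = len(rows[0]) if rows else 0
    metas = []
    for j in range(n_char):
        max_obs = max(
            (max(r[j].states) for r in rows if r[j].states), default=-1
        )
        metas.append(CharacterMeta(index=j, n_states=max(2, max_obs + 1)))
    return CharacterMatrix(taxa=taxa, characters=metas, cells=rows)


def _apply_taxon_table(matrix: CharacterMatrix, path: Path) -> None:
    flags = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1].lower() not in ("extant", "fossil"):
            raise MatrixFormatError(
                f"{path}:{lineno}: expected 'name<TAB>extant|fossil'"
            )
        flags[_norm_name(parts[0])] = parts[1].lower() == "extant"
    for t in matrix.taxa:
        if t.name in flags:
            t.extant = flags[t.name]


# ---------------------------------------------------------------------------
# writing


def _cell_text(cell: CharacterCell, dialect: str) -> str:
    if cell.kind is CellKind.MISSING:
        return "?"
    if cell.kind is CellKind.INAPPLICABLE:
        return "-"
    syms = "".join(state_symbol(s) for s in sorted(cell.states))
    if len(syms) == 1:
        return syms
    return "[" + syms + "]" if dialect == "tnt" else "{" + syms + "}"


def write_matrix(matrix: CharacterMatrix, path, dialect: str = "nexus") -> str:
    """Write ``matrix`` to ``path``; emits a ``.taxa.tsv`` sidecar when any
    taxon is fossil-flagged. Returns the matrix path written."""
    path = Path(path)
    max_states = max((c.n_states for c in matrix.characters), default=2)
    symbols = " ".join(_SYMBOLS[:max_states])
    buf = io.StringIO()
    name_w = max((len(t.name.replace(" ", "_")) for t in matrix.taxa), default=1) + 2
    if dialect == "nexus":
        buf.write("#NEXUS\n\nBEGIN DATA;\n")
        buf.write(
            f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
        )
        buf.write(
            f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n'
        )
        buf.write("    MATRIX\n")
        for t, row in zip(matrix.taxa, matrix.cells):
            cells = "".join(_cell_text(c, "nexus") for c in row)
            buf.write(f"    {t.name.replace(' ', '_'):<{name_w}}{cells}\n")
        buf.write("    ;\nEND;\n")
    elif dialect == "tnt":
        buf.write(f"xread\n{matrix.n_characters} {matrix.n_taxa}\n")
        for t, row in zip(matrix.taxa, matrix.cells):
            cells = "".join(_cell_text(c, "tnt") for c in row)
            buf.write(f"{t.name.replace(' ', '_'):<{name_w}}{cells}\n")
        buf.write(";\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text(buf.getvalue())

    if any(not t.extant for t in matrix.taxa):
        sidecar = path.with_suffix(path.suffix + ".taxa.tsv")
        sidecar.write_text(
            "".join(
                f"{t.name}\t{'extant' if t.extant else 'fossil'}\n"
                for t in matrix.taxa
            )
        )
    return str(path)


# ---------------------------------------------------------------------------
# summary


@dataclass
class MatrixSummary:
    n_taxa: int
    n_characters: int
    n_fossil: int
    missing_fraction: float
    n_parsimony_informative: int


def matrix_summary(matrix: CharacterMatrix) -> MatrixSummary:
    """Counts and coverage. A character is parsimony-informative when at
    least two of its states are each scored (unambiguously) in at least two
    taxa; missing, inapplicable and multi-state cells are ignored for that
    count. The missing fraction counts missing plus inapplicable cells."""
    n_missing = sum(
        1 for row in matrix.cells for c in row if not c.is_observed
    )
    total = matrix.n_taxa * matrix.n_characters
    informative = 0
    for j in range(matrix.n_characters):
        counts: dict = {}
        for row in matrix.cells:
            cell = row[j]
            if cell.is_observed and len(cell.states) == 1:
                (s,) = cell.states
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return MatrixSummary(
        n_taxa=matrix.n_taxa,
        n_characters=matrix.n_characters,
        n_fossil=sum(1 for t in matrix.taxa if not t.extant),
        missing_fraction=(n_missing / total) if total else 0.0,
        n_parsimony_informative=informative,
    )
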