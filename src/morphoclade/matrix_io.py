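"""Discrete morphological character matrices and their text formats.

Cells are one of three things: a :class:`frozenset` of non-negative integer
states (a singleton for a fixed score, more than one entry for a
polymorphism), the :data:`MISSING` sentinel (``?``) or the
:data:`INAPPLICABLE` sentinel (``-``).  The two sentinels are stored
distinctly but both behave as "any state" during parsimony scoring.

Two dialects are supported:

* a TNT ``xread`` block (dimensions line ``nchar ntax``, one row per taxon,
  bracketed polymorphisms, optional ``ccode`` lines for
  ordering/activation/weights using TNT's 0-based character indices);
* a NEXUS ``CHARACTERS``/``DATA`` block with ``DIMENSIONS``, ``FORMAT``
  (``MISSING``/``GAP`` symbols honoured) and ``MATRIX`` commands.

User-facing character indices (``drop_characters`` and the CLI) are 1-based;
internal storage is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return self._name


#: Cell scored as unknown ('?').
MISSING = _Sentinel("MISSING")
#: Cell scored as inapplicable ('-').
INAPPLICABLE = _Sentinel("INAPPLICABLE")

Cell = object  # frozenset[int] | MISSING | INAPPLICABLE


class MatrixFormatError(ValueError):
    """Raised on malformed TNT/NEXUS input; message carries line context."""


@dataclass(frozen=True)
class CharacterMeta:
    """Per-character bookkeeping.

    ``ordered_flag`` marks additive characters (changes cost ``|i - j|``),
    ``active_flag=False`` excludes the character from every length
    computation, ``weight`` multiplies its step count and ``source_label``
    records where the character came from (e.g. the original matrix).
    """

    ordered_flag: bool = False
    active_flag: bool = True
    weight: float = 1.0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"character weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters matrix of discrete states."""

    taxa: tuple[str, ...]
    cells: tuple[tuple[Cell, ...], ...]
    char_meta: tuple[CharacterMeta, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        if any(not t for t in self.taxa):
            raise ValueError("taxon names must be non-empty")
        if len(self.cells) != len(self.taxa):
            raise ValueError(
                f"{len(self.taxa)} taxa but {len(self.cells)} cell rows"
            )
        ncols = {len(row) for row in self.cells}
        if len(ncols) > 1:
            raise ValueError(f"ragged rows: lengths {sorted(ncols)}")
        nchar = ncols.pop() if ncols else 0
        meta = self.char_meta
        if not meta:
            meta = tuple(CharacterMeta() for _ in range(nchar))
            object.__setattr__(self, "char_meta", meta)
        if len(meta) != nchar:
            raise ValueError(
                f"{nchar} characters but {len(meta)} metadata entries"
            )
        for row, taxon in zip(self.cells, self.taxa):
            for j, cell in enumerate(row):
                if cell is MISSING or cell is INAPPLICABLE:
                    continue
                if not isinstance(cell, frozenset) or not cell:
                    raise ValueError(
                        f"cell ({taxon}, char {j + 1}) must be a non-empty "
                        f"frozenset, MISSING or INAPPLICABLE; got {cell!r}"
                    )
                if any((not isinstance(s, int)) or s < 0 for s in cell):
                    raise ValueError(
                        f"cell ({taxon}, char {j + 1}) has non-integer or "
                        f"negative state: {sorted(cell)!r}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> tuple[Cell, ...]:
        try:
            return self.cells[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def column(self, index0: int) -> tuple[Cell, ...]:
        return tuple(row[index0] for row in self.cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and self.char_meta == other.char_meta
        )

    __hash__ = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# cell token helpers


def _cell_from_token(token: str, where: str) -> Cell:
    if token == "?":
        return MISSING
    if token == "-":
        return INAPPLICABLE
    if token.isdigit() or (token.isalpha() and len(token) == 1):
        return frozenset({_state_value(token, where)})
    raise MatrixFormatError(f"unknown state token {token!r} at {where}")


def _state_value(ch: str, where: str) -> int:
    if ch.isdigit():
        return int(ch)
    if ch.isalpha():  # TNT extends states past 9 with letters
        return 10 + (ord(ch.upper()) - ord("A"))
    raise MatrixFormatError(f"unknown state symbol {ch!r} at {where}")


def _cell_to_token(cell: Cell, brackets: str = "[]") -> str:
    if cell is MISSING:
        return "?"
    if cell is INAPPLICABLE:
        return "-"
    syms = "".join(_state_symbol(s) for s in sorted(cell))
    return syms if len(cell) == 1 else f"{brackets[0]}{syms}{brackets[1]}"


def _state_symbol(state: int) -> str:
    if state < 10:
        return str(state)
    if state < 36:
        return chr(ord("A") + state - 10)
    raise ValueError(f"cannot serialise state {state} (max 35)")


def _parse_row_states(text: str, where: str) -> list[Cell]:
    cells: list[Cell] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[" or ch == "(":
            close = "]" if ch == "[" else ")"
            end = text.find(close, i)
            if end < 0:
                raise MatrixFormatError(f"unterminated polymorphism at {where}")
            body = text[i + 1 : end].replace(" ", "")
            if not body:
                raise MatrixFormatError(f"empty polymorphism at {where}")
            cells.append(
                frozenset(_state_value(c, where) for c in body)
            )
            i = end + 1
        else:
            cells.append(_cell_from_token(ch, where))
            i += 1
    return cells


# ---------------------------------------------------------------------------
# TNT dialect


_TNT_COMMENT = re.compile(r"'[^']*'")


def parse_tnt(text: str) -> CharacterMatrix:
    """Parse a TNT ``xread`` data block (plus optional ``ccode`` commands)."""
    stripped = _TNT_COMMENT.sub(" ", text)
    # split into ;-terminated commands
    commands = [c.strip() for c in stripped.split(";")]
    xread = None
    ccodes: list[str] = []
    for cmd in commands:
        if not cmd:
            continue
        head = cmd.split(None, 1)[0].lower()
        if head == "xread":
            xread = cmd
        elif head in ("ccode", "cc"):
            ccodes.append(cmd)
        # other commands (mxram, proc, nstates, ...) are ignored
    if xread is None:
        raise MatrixFormatError("no xread block found")

    tokens = xread.split(None, 3)
    if len(tokens) < 4:
        raise MatrixFormatError("xread block lacks dimensions and rows")
    try:
        nchar, ntax = int(tokens[1]), int(tokens[2])
    except ValueError as exc:
        raise MatrixFormatError(
            f"bad xread dimensions {tokens[1]!r} {tokens[2]!r}"
        ) from exc

    taxa: list[str] = []
    rows: list[tuple[Cell, ...]] = []
    for lineno, line in enumerate(tokens[3].splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(
                f"row line {lineno} ({line[:40]!r}) lacks states"
            )
        name, states = parts
        if name in taxa:
            raise MatrixFormatError(
                f"duplicate taxon name {name!r} at row line {lineno}"
            )
        cells = _parse_row_states(states, f"row line {lineno} ({name})")
        if len(cells) != nchar:
            raise MatrixFormatError(
                f"taxon {name!r} (row line {lineno}) has {len(cells)} "
                f"characters, header declares {nchar}"
            )
        taxa.append(name)
        rows.append(tuple(cells))
    if len(taxa) != ntax:
        raise MatrixFormatError(
            f"header declares {ntax} taxa but {len(taxa)} rows were read"
        )

    meta = [CharacterMeta() for _ in range(nchar)]
    for cmd in ccodes:
        _apply_ccode(cmd, meta)
    return CharacterMatrix(tuple(taxa), tuple(rows), tuple(meta))


def _apply_ccode(cmd: str, meta: list[CharacterMeta]) -> None:
    """Apply a TNT ``ccode`` command (0-based indices, TNT convention).

    Supported flags: ``+`` ordered, ``-`` unordered, ``[`` active,
    ``]`` inactive, ``/N`` weight N.  ``a.b`` index ranges and ``.`` (all
    characters) are accepted.
    """
    body = cmd.split(None, 1)
    if len(body) < 2:
        return
    tokens = re.findall(r"/\d+|[+\-\[\]]|\d+\.\d+|\d+|\.", body[1])
    state: dict[str, object] = {}
    for tok in tokens:
        if tok == "+":
            state["ordered_flag"] = True
        elif tok == "-":
            state["ordered_flag"] = False
        elif tok == "[":
            state["active_flag"] = True
        elif tok == "]":
            state["active_flag"] = False
        elif tok.startswith("/"):
            state["weight"] = float(tok[1:])
        else:
            if tok == ".":
                idx = range(len(meta))
            elif "." in tok:
                lo, hi = tok.split(".")
                idx = range(int(lo), int(hi) + 1)
            else:
                idx = range(int(tok), int(tok) + 1)
            for i in idx:
                if not 0 <= i < len(meta):
                    raise MatrixFormatError(
                        f"ccode index {i} out of range (0..{len(meta) - 1})"
                    )
                meta[i] = replace(meta[i], **state)  # type: ignore[arg-type]


def write_tnt(matrix: CharacterMatrix) -> str:
    """Serialise to TNT; ``parse_tnt(write_tnt(m)) == m`` up to source labels."""
    lines = ["xread", f"{matrix.n_characters} {matrix.n_taxa}"]
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        states = "".join(_cell_to_token(c) for c in row)
        lines.append(f"{taxon:<{width}}{states}")
    lines.append(";")
    ccode = _ccode_lines(matrix.char_meta)
    lines.extend(ccode)
    lines.append("proc /;")
    return "\n".join(lines) + "\n"


def _ccode_lines(meta: Sequence[CharacterMeta]) -> list[str]:
    parts: list[str] = []
    ordered = [i for i, m in enumerate(meta) if m.ordered_flag]
    inactive = [i for i, m in enumerate(meta) if not m.active_flag]
    weighted = [(i, m.weight) for i, m in enumerate(meta) if m.weight != 1.0]
    if ordered:
        parts.append("ccode + " + " ".join(map(str, ordered)) + ";")
    if inactive:
        parts.append("ccode ] " + " ".join(map(str, inactive)) + ";")
    for i, w in weighted:
        if w != int(w):
            raise ValueError(
                f"TNT ccode weights must be integers; char {i} has weight {w}"
            )
        parts.append(f"ccode /{int(w)} {i};")
    return parts


# ---------------------------------------------------------------------------
# NEXUS dialect


def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS ``CHARACTERS`` or ``DATA`` block (standard datatype)."""
    stripped = re.sub(r"\[[^\]]*\]", " ", text)  # NEXUS comments
    m = re.search(
        r"begin\s+(characters|data)\s*;(.*?)end\s*;",
        stripped,
        re.IGNORECASE | re.DOTALL,
    )
    if not m:
        raise MatrixFormatError("no CHARACTERS/DATA block found")
    block = m.group(2)

    dim = re.search(
        r"dimensions([^;]*);", block, re.IGNORECASE | re.DOTALL
    )
    if not dim:
        raise MatrixFormatError("CHARACTERS block lacks DIMENSIONS")
    ntax = _nexus_int(dim.group(1), "ntax")
    nchar = _nexus_int(dim.group(1), "nchar")

    missing_sym, gap_sym, symbols = "?", "-", None
    fmt = re.search(r"format([^;]*);", block, re.IGNORECASE | re.DOTALL)
    if fmt:
        body = fmt.group(1)
        mm = re.search(r"missing\s*=\s*(\S)", body, re.IGNORECASE)
        if mm:
            missing_sym = mm.group(1)
        gm = re.search(r"gap\s*=\s*(\S)", body, re.IGNORECASE)
        if gm:
            gap_sym = gm.group(1)
        sm = re.search(r'symbols\s*=\s*"([^"]*)"', body, re.IGNORECASE)
        if sm:
            symbols = set(sm.group(1).replace(" ", ""))

    mat = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mat:
        raise MatrixFormatError("CHARACTERS block lacks MATRIX")

    taxa: list[str] = []
    rows: list[tuple[Cell, ...]] = []
    for lineno, line in enumerate(mat.group(1).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        name_m = re.match(r"('(?:[^']*)'|\S+)\s+(.*)", line)
        if not name_m:
            raise MatrixFormatError(f"bad matrix row at line {lineno}: {line!r}")
        name = name_m.group(1).strip("'")
        states_txt = name_m.group(2).replace("{", "(").replace("}", ")")
        where = f"matrix line {lineno} ({name})"
        translated = []
        for ch in states_txt:
            if ch == missing_sym:
                translated.append("?")
            elif ch == gap_sym:
                translated.append("-")
            else:
                if (
                    symbols is not None
                    and ch not in symbols
                    and ch not in "()[] \t"
                ):
                    raise MatrixFormatError(
                        f"symbol {ch!r} outside declared SYMBOLS at {where}"
                    )
                translated.append(ch)
        cells = _parse_row_states("".join(translated), where)
        if len(cells) != nchar:
            raise MatrixFormatError(
                f"taxon {name!r} has {len(cells)} characters, "
                f"DIMENSIONS declares {nchar}"
            )
        if name in taxa:
            raise MatrixFormatError(f"duplicate taxon name {name!r} at {where}")
        taxa.append(name)
        rows.append(tuple(cells))
    if len(taxa) != ntax:
        raise MatrixFormatError(
            f"DIMENSIONS declares {ntax} taxa but {len(taxa)} rows were read"
        )
    return CharacterMatrix(tuple(taxa), tuple(rows))


def _nexus_int(body: str, key: str) -> int:
    m = re.search(rf"{key}\s*=\s*(\d+)", body, re.IGNORECASE)
    if not m:
        raise MatrixFormatError(f"DIMENSIONS lacks {key.upper()}")
    return int(m.group(1))


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialise to a NEXUS CHARACTERS block (ordering emitted as TYPESET)."""
    states = sorted(
        {
            s
            for row in matrix.cells
            for cell in row
            if isinstance(cell, frozenset)
            for s in cell
        }
    )
    symbols = " ".join(_state_symbol(s) for s in states) or "0 1"
    lines = [
        "#NEXUS",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{symbols}";',
        "  MATRIX",
    ]
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        name = f"'{taxon}'" if re.search(r"\s", taxon) else taxon
        # polymorphisms use () so they survive NEXUS [comment] stripping
        lines.append(
            f"    {name:<{width}}"
            + "".join(_cell_to_token(c, "()") for c in row)
        )
    lines.append("  ;")
    lines.append("END;")
    ordered = [i + 1 for i, m in enumerate(matrix.char_meta) if m.ordered_flag]
    if ordered:
        lines.append("BEGIN ASSUMPTIONS;")
        lines.append(
            "  TYPESET * default = ord: " + " ".join(map(str, ordered)) + ";"
        )
        lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# editing / merging


def drop_characters(
    matrix: CharacterMatrix, indices: Iterable[int]
) -> CharacterMatrix:
    """Remove characters by 1-based index, preserving the rest in order."""
    idx = list(indices)
    if len(idx) != len(set(idx)):
        raise ValueError(f"duplicate character indices: {sorted(idx)}")
    for i in idx:
        if not 1 <= i <= matrix.n_characters:
            raise ValueError(
                f"character index {i} out of range 1..{matrix.n_characters}"
            )
    drop0 = {i - 1 for i in idx}
    keep = [j for j in range(matrix.n_characters) if j not in drop0]
    return CharacterMatrix(
        matrix.taxa,
        tuple(tuple(row[j] for j in keep) for row in matrix.cells),
        tuple(matrix.char_meta[j] for j in keep),
    )


def drop_taxa(matrix: CharacterMatrix, names: Iterable[str]) -> CharacterMatrix:
    """Remove taxa by name; character count is unchanged."""
    names = list(names)
    unknown = [n for n in names if n not in matrix.taxa]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    gone = set(names)
    keep = [i for i, t in enumerate(matrix.taxa) if t not in gone]
    return CharacterMatrix(
        tuple(matrix.taxa[i] for i in keep),
        tuple(matrix.cells[i] for i in keep),
        matrix.char_meta,
    )


def merge_matrices(
    a: CharacterMatrix, b: CharacterMatrix
) -> CharacterMatrix:
    """Concatenate character blocks of two matrices over identical taxon sets.

    Taxa must already be harmonised (same set, any order); the result keeps
    ``a``'s taxon order with ``a``'s characters first.
    """
    if set(a.taxa) != set(b.taxa):
        only_a = sorted(set(a.taxa) - set(b.taxa))
        only_b = sorted(set(b.taxa) - set(a.taxa))
        raise ValueError(
            f"taxon sets differ; only in first: {only_a}, "
            f"only in second: {only_b}"
        )
    b_index = {t: i for i, t in enumerate(b.taxa)}
    rows = tuple(
        a.cells[i] + b.cells[b_index[t]] for i, t in enumerate(a.taxa)
    )
    return CharacterMatrix(a.taxa, rows, a.char_meta + b.char_meta)


def relabel_meta(matrix: CharacterMatrix, source_label: str) -> CharacterMatrix:
    """Return a copy whose every character carries ``source_label``."""
    meta = tuple(
        replace(m, source_label=source_label) for m in matrix.char_meta
    )
    return CharacterMatrix(matrix.taxa, matrix.cells, meta)
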