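"""Readers and writers for the formats the pipeline touches.

Character matrices come in as TNT ``xread`` blocks (the dialect used for
morphological supplementary data) or as a read-only subset of NEXUS
``CHARACTERS`` blocks.  Trees are plain Newick, handled through dendropy.
Tip-age and head-width/total-length measurement tables are delimited text
with documented headers.

Conventions
-----------
* Discrete states are small non-negative integers.  The TNT reader accepts
  the common morphological dialect (states ``0``-``9``), which keeps row
  boundaries unambiguous when rows wrap; the NEXUS reader additionally maps
  ``A``-``Z`` to 10-35.
* ``?`` and ``-`` (inapplicable) are both treated as missing: the cell's
  ambiguity set is empty and the cell is free to take any state in parsimony.
* Bracketed scores like ``[01]`` are polymorphism-as-uncertainty: the cell may
  take any of the listed states.
* Lengths are centimetres, ages are Ma (million years before present).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: marker for a missing / inapplicable cell
MISSING: frozenset[int] = frozenset()

AGE_COLUMNS = ("taxon", "fad", "lad")
ALLOMETRY_COLUMNS = ("taxon", "specimen", "hw_cm", "tl_cm")


class ParseError(ValueError):
    """Raised when a matrix, tree or table cannot be parsed."""


class SchemaError(ValueError):
    """Raised when a delimited table lacks required columns or valid rows."""


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """A taxa x discrete-characters matrix with ambiguity sets.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    cells:
        ``cells[i][j]`` is the ambiguity set (frozenset of int states) of
        taxon *i* at character *j*; the empty set marks missing data.
    ordered:
        Per-character flag; ``True`` for morphocline (Wagner / ordered)
        characters, ``False`` for unordered (Fitch) characters.
    """

    taxa: list[str]
    cells: list[list[frozenset[int]]]
    ordered: list[bool] = field(default_factory=list)
    state_labels: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ParseError("duplicate taxon labels in matrix")
        if len(self.cells) != len(self.taxa):
            raise ParseError("cells row count does not match taxon count")
        lengths = {len(row) for row in self.cells}
        if len(lengths) > 1:
            raise ParseError(f"unequal row lengths: {sorted(lengths)}")
        if not self.ordered:
            self.ordered = [False] * self.n_chars
        if len(self.ordered) != self.n_chars:
            raise ParseError("ordered flags length does not match n_chars")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def column(self, j: int) -> list[frozenset[int]]:
        return [row[j] for row in self.cells]

    def state_universe(self, j: int) -> frozenset[int]:
        """All states observed for character *j* across taxa."""
        states: set[int] = set()
        for row in self.cells:
            states |= row[j]
        return frozenset(states)

    def n_states(self, j: int) -> int:
        """Size of the 0..max contiguous state range for character *j*."""
        universe = self.state_universe(j)
        return (max(universe) + 1) if universe else 1

    def row(self, taxon: str) -> list[frozenset[int]]:
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None
        return self.cells[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and self.ordered == other.ordered
        )


_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_STATE_OF = {s: i for i, s in enumerate(_SYMBOLS)}
_STATE_OF.update({s.lower(): i for i, s in enumerate(_SYMBOLS) if s.isalpha()})


#: symbols accepted in TNT rows: the common morphological dialect (states 0-9)
_TNT_ROW_CHARS = set("0123456789?-[")


def _symbol_to_state(sym: str, pos: int) -> frozenset[int]:
    if sym in "?-":
        return MISSING
    if sym in _STATE_OF:
        return frozenset([_STATE_OF[sym]])
    raise ParseError(f"undeclared state symbol {sym!r} at position {pos}")


def _tnt_symbol_to_state(sym: str, pos: int) -> frozenset[int]:
    if sym in "?-":
        return MISSING
    if sym.isdigit():
        return frozenset([int(sym)])
    raise ParseError(f"undeclared state symbol {sym!r} at position {pos}")


def read_tnt_matrix(path: str | Path) -> CharacterMatrix:
    """Parse a TNT ``xread`` block into a :class:`CharacterMatrix`.

    Only the ``xread`` block and ordered/unordered ``ccode`` directives are
    interpreted; any other TNT command in the file is ignored with a logged
    warning.  Interleaved (``&``-separated) blocks are not supported: each
    taxon's full character string must follow its name, though it may wrap
    across lines.
    """
    text = Path(path).read_text()
    m = re.search(r"\bxread\b", text)
    if m is None:
        raise ParseError(f"{path}: no xread block found")
    i = m.end()
    n = len(text)

    def skip_ws(i: int) -> int:
        while i < n and text[i].isspace():
            i += 1
        return i

    i = skip_ws(i)
    # optional quoted title
    if i < n and text[i] == "'":
        j = text.find("'", i + 1)
        if j < 0:
            raise ParseError(f"{path}: unterminated xread title")
        i = skip_ws(j + 1)

    def read_int(i: int, what: str) -> tuple[int, int]:
        j = i
        while j < n and text[j].isdigit():
            j += 1
        if j == i:
            raise ParseError(f"{path}: expected {what} at offset {i}")
        return int(text[i:j]), skip_ws(j)

    n_chars, i = read_int(i, "character count")
    n_taxa, i = read_int(i, "taxon count")

    taxa: list[str] = []
    cells: list[list[frozenset[int]]] = []
    while True:
        i = skip_ws(i)
        if i >= n:
            raise ParseError(f"{path}: xread block not terminated by ';'")
        if text[i] == ";":
            i += 1
            break
        if text[i] == "&":
            raise ParseError(f"{path}: interleaved xread blocks are not supported")
        # taxon name token
        j = i
        while j < n and not text[j].isspace():
            j += 1
        name = text[i:j]
        i = j
        row: list[frozenset[int]] = []
        while len(row) < n_chars:
            i = skip_ws(i)
            ch = text[i] if i < n else ";"
            if ch == ";" or ch.isalpha() or ch == "_":
                # a terminator or the start of the next taxon's name
                raise ParseError(
                    f"{path}: taxon {name!r} has {len(row)} of {n_chars} characters"
                )
            if ch not in _TNT_ROW_CHARS:
                raise ParseError(f"{path}: undeclared state symbol {ch!r} at position {i}")
            if ch == "[":
                j = text.find("]", i)
                if j < 0:
                    raise ParseError(f"{path}: unterminated '[' at offset {i}")
                group: set[int] = set()
                for k, sym in enumerate(text[i + 1 : j]):
                    if sym.isspace():
                        continue
                    group |= _tnt_symbol_to_state(sym, i + 1 + k)
                row.append(frozenset(group))
                i = j + 1
            else:
                row.append(_tnt_symbol_to_state(ch, i))
                i += 1
        taxa.append(name)
        cells.append(row)

    if len(taxa) != n_taxa:
        raise ParseError(f"{path}: declared {n_taxa} taxa but parsed {len(taxa)}")

    ordered = _parse_ccode(text[i:], n_chars)
    _warn_ignored_commands(text[i:], path)
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=ordered)


def _parse_ccode(tail: str, n_chars: int) -> list[bool]:
    """Extract ordered flags from ``ccode`` directives after the xread block.

    Supported tokens: ``+`` (following characters ordered/additive), ``-``
    (unordered), bare indices, ``a.b`` ranges and ``.`` (all characters).
    Activity (``[``/``]``) and weight (``/``) tokens are skipped.
    """
    ordered = [False] * n_chars
    for m in re.finditer(r"\bccode\b([^;]*);", tail, flags=re.IGNORECASE):
        flag: bool | None = None
        for tok in m.group(1).split():
            if tok == "+":
                flag = True
            elif tok == "-":
                flag = False
            elif tok in ("[", "]") or tok.startswith("/"):
                continue
            elif tok == ".":
                if flag is not None:
                    ordered = [flag] * n_chars
            elif re.fullmatch(r"\d+\.\d+", tok):
                a, b = (int(x) for x in tok.split("."))
                if flag is not None:
                    for k in range(a, min(b, n_chars - 1) + 1):
                        ordered[k] = flag
            elif tok.isdigit():
                k = int(tok)
                if flag is not None and k < n_chars:
                    ordered[k] = flag
    return ordered


def _warn_ignored_commands(tail: str, path: str | Path) -> None:
    for m in re.finditer(r"\b([a-z]+)\b[^;]*;", tail, flags=re.IGNORECASE):
        cmd = m.group(1).lower()
        if cmd not in ("ccode", "proc", "procedure", "xread", "nstates", "comments"):
            logger.warning("%s: ignoring TNT command %r", path, cmd)


def write_tnt_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write *matrix* as an ``xread`` block plus a ``ccode`` directive."""
    lines = [f"xread {matrix.n_chars} {matrix.n_taxa}"]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        parts = []
        for cell in row:
            if not cell:
                parts.append("?")
            elif len(cell) == 1:
                parts.append(_SYMBOLS[next(iter(cell))])
            else:
                parts.append("[" + "".join(_SYMBOLS[s] for s in sorted(cell)) + "]")
        lines.append(f"{taxon} {''.join(parts)}")
    lines.append(";")
    ordered_idx = [str(j) for j, flag in enumerate(matrix.ordered) if flag]
    if ordered_idx:
        lines.append("ccode + " + " ".join(ordered_idx) + " ;")
    lines.append("proc /;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nexus_matrix(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS ``CHARACTERS``/``DATA`` block (read-only subset).

    Ordering flags are taken from a ``TYPESET`` line with an ``ord:`` list if
    present; otherwise all characters are unordered.
    """
    data = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    taxa = [t.label for t in data.taxon_namespace]
    cells: list[list[frozenset[int]]] = []
    for taxon in data.taxon_namespace:
        row: list[frozenset[int]] = []
        for cell in data[taxon]:
            syms = [ms.symbol for ms in cell.fundamental_states]
            if any(s in "?-" for s in syms):
                row.append(MISSING)
            else:
                row.append(frozenset(_STATE_OF[s] for s in syms))
        cells.append(row)
    n_chars = len(cells[0]) if cells else 0
    ordered = [False] * n_chars
    text = Path(path).read_text()
    m = re.search(r"typeset[^;]*\bord\s*:\s*([0-9\s.\-]+)", text, flags=re.IGNORECASE)
    if m:
        for tok in m.group(1).split():
            if re.fullmatch(r"\d+", tok):
                k = int(tok) - 1  # NEXUS is 1-based
                if 0 <= k < n_chars:
                    ordered[k] = True
            elif re.fullmatch(r"\d+-\d+", tok):
                a, b = (int(x) for x in tok.split("-"))
                for k in range(a - 1, min(b, n_chars)):
                    ordered[k] = True
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=ordered)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving labels and polytomies.

    *source* may be a path or a literal Newick string (detected by the
    presence of ``(`` or ``;``).
    """
    text = str(source)
    if "(" in text or ";" in text:
        data, kind = text, "data"
    else:
        data, kind = Path(source).read_text(), "data"
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    del kind
    return tree


def read_newick_list(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one tree per ';')."""
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return list(trees)


def write_newick(tree: dendropy.Tree, path: str | Path, *, branch_lengths: bool = True) -> None:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=not branch_lengths,
    )
    Path(path).write_text(s)


def write_newick_list(trees: Sequence[dendropy.Tree], path: str | Path) -> None:
    parts = [
        t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=True,
        ).strip()
        for t in trees
    ]
    Path(path).write_text("\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllometryRecord:
    """One specimen's measurements: head width and (for extant) total length, cm."""

    taxon: str
    specimen: str
    hw_cm: float
    tl_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.hw_cm > 0:
            raise SchemaError(f"{self.taxon}/{self.specimen}: hw_cm must be > 0")
        if self.tl_cm is not None and not self.tl_cm > 0:
            raise SchemaError(f"{self.taxon}/{self.specimen}: tl_cm must be > 0")


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path, schema: str) -> pd.DataFrame | list[AllometryRecord]:
    """Read a delimited table.

    ``schema='age'`` returns a DataFrame with columns ``taxon, fad, lad``
    (Ma), validated so ``fad >= lad >= 0`` with one row per taxon.
    ``schema='allometry'`` returns a list of :class:`AllometryRecord`
    (``tl_cm`` may be blank for fossils).
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if schema == "age":
        missing = [c for c in AGE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: age table missing columns {missing}")
        for idx, row in df.iterrows():
            line = idx + 2  # header is line 1
            try:
                fad, lad = float(row["fad"]), float(row["lad"])
            except (TypeError, ValueError):
                raise SchemaError(f"{path}:{line}: non-numeric age") from None
            if not (fad >= lad >= 0):
                raise SchemaError(
                    f"{path}:{line}: require fad >= lad >= 0, got fad={fad}, lad={lad}"
                )
        if df["taxon"].duplicated().any():
            dups = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
            raise SchemaError(f"{path}: duplicate taxa in age table: {dups}")
        df["fad"] = df["fad"].astype(float)
        df["lad"] = df["lad"].astype(float)
        return df[list(AGE_COLUMNS)]
    if schema == "allometry":
        required = ("taxon", "hw_cm")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: allometry table missing columns {missing}")
        if "specimen" not in df.columns:
            df["specimen"] = [str(i + 1) for i in range(len(df))]
        records: list[AllometryRecord] = []
        for idx, row in df.iterrows():
            line = idx + 2
            try:
                hw = float(row["hw_cm"])
                tl = row.get("tl_cm")
                tl = None if tl is None or pd.isna(tl) else float(tl)
            except (TypeError, ValueError):
                raise SchemaError(f"{path}:{line}: non-numeric measurement") from None
            try:
                records.append(
                    AllometryRecord(
                        taxon=str(row["taxon"]),
                        specimen=str(row["specimen"]),
                        hw_cm=hw,
                        tl_cm=tl,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{path}:{line}: {exc}") from None
        return records
    raise ValueError(f"unknown schema {schema!r}; expected 'age' or 'allometry'")


def write_age_table(ages: pd.DataFrame, path: str | Path) -> None:
    ages[list(AGE_COLUMNS)].to_csv(path, index=False)


def write_allometry_table(records: Iterable[AllometryRecord], path: str | Path) -> None:
    rows = [
        {
            "taxon": r.taxon,
            "specimen": r.specimen,
            "hw_cm": r.hw_cm,
            "tl_cm": "" if r.tl_cm is None else r.tl_cm,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ALLOMETRY_COLUMNS)).to_csv(path, index=False)
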