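"""Reading and writing character matrices, tree files and tabular outputs.

The matrix reader targets the TNT ``xread`` dialect as exported by MorphoBank
(state symbols 0-9, ``-`` for inapplicable, ``?`` for missing, bracketed
polymorphisms) and keeps any trailing command blocks (``ccode``, ``cnames``,
``xlinks`` ...) verbatim so dependency annotations survive a round trip.
NEXUS character blocks are read through dendropy.  All character indices are
0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .trees import PhyloTree


class _Token:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: A cell that could not be observed.
MISSING = _Token("MISSING")
#: A cell where no state logically applies (controller in a disabling state).
INAPPLICABLE = _Token("INAPPLICABLE")

CellValue = Union[int, FrozenSet[int], _Token]


class MatrixParseError(ValueError):
    """Raised for malformed matrix input, with row/column context."""


@dataclass(frozen=True)
class Character:
    """One column of the matrix.

    Neomorphic characters are two-state absence/presence statements (state 0
    = absent); transformational characters describe conditions of a structure
    assumed present.  ``weight`` is an exact rational so that ten-fold
    upweighting combined with serial-homologue discounts stays tie-exact.
    """

    index: int
    statement: str = ""
    char_type: str = "transformational"  # or "neomorphic"
    state_codes: Tuple[int, ...] = (0, 1)
    weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if self.char_type not in ("neomorphic", "transformational"):
            raise ValueError(f"unknown char_type {self.char_type!r}")
        if self.char_type == "neomorphic" and len(self.state_codes) != 2:
            raise ValueError("neomorphic characters have exactly 2 states")
        if self.weight <= 0:
            raise ValueError("character weight must be positive")


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of discrete scorings."""

    taxon_labels: List[str]
    characters: List[Character]
    cells: List[List[CellValue]]  # indexed [taxon][character]
    source_commands: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValueError("taxon labels must be unique")
        if len(self.cells) != len(self.taxon_labels):
            raise ValueError("cell grid rows != number of taxa")
        for t, row in enumerate(self.cells):
            if len(row) != len(self.characters):
                raise ValueError(
                    f"row for taxon {self.taxon_labels[t]!r} has {len(row)} cells,"
                    f" expected {len(self.characters)}"
                )
        for c, ch in enumerate(self.characters):
            if ch.index != c:
                raise ValueError("character indices must be contiguous from 0")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def n_cells(self) -> int:
        return self.n_taxa * self.n_characters

    def cell(self, taxon: Union[int, str], char: int) -> CellValue:
        if isinstance(taxon, str):
            taxon = self.taxon_labels.index(taxon)
        return self.cells[taxon][char]

    def column(self, char: int) -> Dict[str, CellValue]:
        return {t: self.cells[i][char] for i, t in enumerate(self.taxon_labels)}

    def count_missing(self) -> int:
        return sum(c is MISSING for row in self.cells for c in row)

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.taxon_labels),
            list(self.characters),
            [list(row) for row in self.cells],
            list(self.source_commands),
        )

    def with_weights(self, weights: Mapping[int, Fraction]) -> "CharacterMatrix":
        chars = [
            replace(ch, weight=Fraction(weights.get(ch.index, ch.weight)))
            for ch in self.characters
        ]
        return CharacterMatrix(
            list(self.taxon_labels), chars, [list(r) for r in self.cells],
            list(self.source_commands),
        )


# ---------------------------------------------------------------------------
# TNT xread dialect
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _normalise_label(raw: str) -> str:
    return _WS.sub("_", raw.strip().strip("'\"‘’“”"))


def _as_text(path_or_text: Union[str, os.PathLike]) -> str:
    if isinstance(path_or_text, os.PathLike):
        return Path(path_or_text).read_text()
    if "\n" in path_or_text or "xread" in path_or_text.lower():
        return path_or_text
    p = Path(path_or_text)
    if p.exists():
        return p.read_text()
    return path_or_text


def _parse_symbols(
    stream: str, n_expected: int, taxon: str
) -> List[CellValue]:
    out: List[CellValue] = []
    i = 0
    while i < len(stream):
        ch = stream[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "?":
            out.append(MISSING)
        elif ch == "-":
            out.append(INAPPLICABLE)
        elif ch.isdigit():
            out.append(int(ch))
        elif ch in "([":
            close = ")" if ch == "(" else "]"
            j = stream.find(close, i)
            if j < 0:
                raise MatrixParseError(
                    f"unterminated polymorphism for taxon {taxon!r}"
                )
            states = frozenset(int(c) for c in stream[i + 1 : j] if c.isdigit())
            if len(states) < 2:
                raise MatrixParseError(
                    f"polymorphism with fewer than 2 states for taxon {taxon!r}"
                )
            out.append(states)
            i = j
        else:
            raise MatrixParseError(
                f"unknown symbol {ch!r} at column {len(out) + 1} of taxon {taxon!r}"
            )
        i += 1
    if len(out) != n_expected:
        raise MatrixParseError(
            f"taxon {taxon!r} has {len(out)} cells, header declares {n_expected}"
        )
    return out


_CCODE_W = re.compile(r"^ccode\s*/\s*(\d+(?:\.\d+)?)\s+(.*?);?\s*$", re.I)
_CNAMES_ENTRY = re.compile(r"\{\s*(\d+)\s+([^;]*);")


def _parse_char_selector(sel: str, n_char: int) -> List[int]:
    """TNT-style character selection: 'a.b' is an inclusive 0-based range,
    'a' a single character, '.' everything; space-separated terms union."""
    idx: List[int] = []
    for term in sel.split():
        if term == ".":
            idx.extend(range(n_char))
        elif "." in term:
            a, b = term.split(".", 1)
            idx.extend(range(int(a), int(b) + 1))
        else:
            idx.append(int(term))
    for i in idx:
        if not 0 <= i < n_char:
            raise MatrixParseError(f"character {i} out of range in selector {sel!r}")
    return idx


def read_tnt_matrix(
    path_or_text: Union[str, os.PathLike],
    dialect_options: Optional[Mapping[str, object]] = None,
) -> CharacterMatrix:
    """Parse an ``xread`` block plus trailing command lines.

    The header is ``xread ['title'] NCHAR NTAX`` (character count first, per
    TNT convention).  ``ccode /w sel;`` commands set weights, ``cnames``
    entries ``{i text;`` set character statements; both are also retained
    verbatim in ``source_commands`` together with any other command lines
    (e.g. ``xlinks`` blocks).
    """
    del dialect_options  # single documented dialect; hook kept for API stability
    text = _as_text(path_or_text)
    m = re.search(r"\bxread\b", text, re.I)
    if not m:
        raise MatrixParseError("no xread block found")
    rest = text[m.end() :]
    title = None
    tm = re.match(r"\s*'([^']*)'", rest)
    if tm:
        title = tm.group(1)
        rest = rest[tm.end() :]
    hm = re.match(r"\s*(\d+)\s+(\d+)\s*", rest)
    if not hm:
        raise MatrixParseError("xread header must declare NCHAR NTAX")
    n_char, n_taxa = int(hm.group(1)), int(hm.group(2))
    rest = rest[hm.end() :]
    end = rest.find(";")
    if end < 0:
        raise MatrixParseError("unterminated xread data block (missing ';')")
    data_block, command_block = rest[:end], rest[end + 1 :]

    taxon_labels: List[str] = []
    rows: List[List[CellValue]] = []
    lines = [ln for ln in data_block.splitlines() if ln.strip()]
    for ln in lines:
        stripped = ln.lstrip()
        if stripped[:1] in ("'", '"'):
            quote = stripped[0]
            close = stripped.find(quote, 1)
            if close < 0:
                raise MatrixParseError(f"unterminated quoted label in row {ln!r}")
            parts = [stripped[1:close], stripped[close + 1 :]]
        else:
            parts = stripped.split(None, 1)
        if len(parts) < 2 or not parts[1].strip():
            raise MatrixParseError(f"data row {ln!r} has no cells")
        label = _normalise_label(parts[0])
        if label in taxon_labels:
            raise MatrixParseError(f"duplicate taxon label {label!r}")
        taxon_labels.append(label)
        rows.append(_parse_symbols(parts[1], n_char, label))
    if len(taxon_labels) != n_taxa:
        raise MatrixParseError(
            f"found {len(taxon_labels)} taxa, header declares {n_taxa}"
        )

    # infer state codes per character from the observed cells
    observed: List[set] = [set() for _ in range(n_char)]
    for row in rows:
        for c, cell in enumerate(row):
            if isinstance(cell, int):
                observed[c].add(cell)
            elif isinstance(cell, frozenset):
                observed[c] |= cell

    commands: List[str] = []
    weights: Dict[int, Fraction] = {}
    statements: Dict[int, str] = {}
    for raw in re.split(r"(?<=;)", command_block):
        cmd = raw.strip()
        if not cmd or cmd.lower() in ("proc/;", "proc /;", "proc;"):
            continue
        commands.append(cmd)
        wm = _CCODE_W.match(cmd)
        if wm:
            w = Fraction(wm.group(1))
            for i in _parse_char_selector(wm.group(2), n_char):
                weights[i] = w
        if cmd.lower().startswith("cnames") or cmd.startswith("{"):
            for em in _CNAMES_ENTRY.finditer(cmd):
                i = int(em.group(1))
                if not 0 <= i < n_char:
                    raise MatrixParseError(f"cnames entry for character {i} out of range")
                statements[i] = em.group(2).strip().strip("'")

    characters: List[Character] = []
    for c in range(n_char):
        full = tuple(range(0, max(observed[c], default=1) + 1))
        if len(full) < 2:
            full = (0, 1)
        stmt = statements.get(c, "")
        ctype = (
            "neomorphic"
            if len(full) == 2 and re.search(r"\(0\)\s*absent", stmt)
            else "transformational"
        )
        characters.append(
            Character(
                index=c,
                statement=stmt,
                char_type=ctype,
                state_codes=full,
                weight=weights.get(c, Fraction(1)),
            )
        )
    del title  # tolerated but not carried on the in-memory matrix
    return CharacterMatrix(taxon_labels, characters, rows, commands)


def write_tnt_matrix(matrix: CharacterMatrix, include_commands: bool = True) -> str:
    """Serialize to the xread dialect; ``read_tnt_matrix`` round-trips the
    result cell-for-cell, including weights and statements."""
    out = [f"xread {matrix.n_characters} {matrix.n_taxa}"]
    width = max((len(t) for t in matrix.taxon_labels), default=0) + 2
    for t, row in zip(matrix.taxon_labels, matrix.cells):
        cells = []
        for cell in row:
            if cell is MISSING:
                cells.append("?")
            elif cell is INAPPLICABLE:
                cells.append("-")
            elif isinstance(cell, frozenset):
                cells.append("[" + "".join(str(s) for s in sorted(cell)) + "]")
            else:
                cells.append(str(cell))
        out.append(t.ljust(width) + "".join(cells))
    out.append(";")
    existing = "\n".join(matrix.source_commands).lower()
    if include_commands:
        out.extend(matrix.source_commands)
    by_weight: Dict[Fraction, List[int]] = {}
    for ch in matrix.characters:
        if ch.weight != 1:
            by_weight.setdefault(ch.weight, []).append(ch.index)
    if by_weight and "ccode" not in existing:
        for w in sorted(by_weight):
            sel = " ".join(str(i) for i in by_weight[w])
            out.append(f"ccode /{w} {sel};")
    if any(ch.statement for ch in matrix.characters) and "cnames" not in existing:
        entries = "".join(
            f"\n{{{ch.index} {ch.statement};"
            for ch in matrix.characters
            if ch.statement
        )
        out.append(f"cnames{entries}\n;")
    out.append("proc/;")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# NEXUS characters
# ---------------------------------------------------------------------------

def read_nexus_matrix(path_or_text: Union[str, os.PathLike]) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block (standard datatype) via dendropy.

    ``-`` (gap) maps to INAPPLICABLE and ``?`` to MISSING.
    """
    text = _as_text(path_or_text) if not isinstance(path_or_text, os.PathLike) else None
    if text is not None and not text.lstrip().startswith("#"):
        # looked like a path but was not; treat as text anyway
        pass
    src = {"data": text} if text is not None else {"path": str(path_or_text)}
    dm = dendropy.StandardCharacterMatrix.get(schema="nexus", **src)
    taxon_labels = [_normalise_label(t.label) for t in dm.taxon_namespace]
    n_char = max(len(dm[t]) for t in dm.taxon_namespace)
    rows: List[List[CellValue]] = []
    observed: List[set] = [set() for _ in range(n_char)]
    for t in dm.taxon_namespace:
        row: List[CellValue] = []
        for c, v in enumerate(dm[t]):
            sym = str(v)
            if sym in ("?",):
                row.append(MISSING)
            elif sym == "-":
                row.append(INAPPLICABLE)
            elif sym.isdigit():
                row.append(int(sym))
                observed[c].add(int(sym))
            else:
                states = frozenset(
                    int(s) for s in re.findall(r"\d", sym)
                )
                if len(states) >= 2:
                    row.append(states)
                    observed[c] |= states
                else:
                    raise MatrixParseError(
                        f"unsupported NEXUS symbol {sym!r} for taxon {t.label!r}"
                    )
        rows.append(row)
    characters = [
        Character(
            index=c,
            state_codes=tuple(range(max(observed[c] | {1}) + 1)),
        )
        for c in range(n_char)
    ]
    return CharacterMatrix(taxon_labels, characters, rows)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_trees(
    path_or_text: Union[str, os.PathLike],
    taxon_labels: Optional[Sequence[str]] = None,
) -> List[PhyloTree]:
    """Read Newick (or NEXUS TREES) files into unrooted trees.

    When ``taxon_labels`` is given, integer leaf labels are interpreted as
    1-based indices into it (translate-table dialect), and every tree is
    required to have exactly that leaf set.
    """
    text = _as_text(path_or_text)
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    tlist = dendropy.TreeList.get(data=text, schema=schema, preserve_underscores=True)
    out: List[PhyloTree] = []
    for t in tlist:
        tree = PhyloTree.from_newick(t.as_string(schema="newick"))
        if taxon_labels is not None:
            mapping = {}
            if all(lab.isdigit() for lab in tree.leaf_set):
                for v, lab in tree.leaf_ids.items():
                    i = int(lab) - 1
                    if not 0 <= i < len(taxon_labels):
                        raise ValueError(f"leaf index {lab} out of range")
                    mapping[v] = taxon_labels[i]
                tree = PhyloTree(tree.adjacency, mapping)
            unknown = tree.leaf_set - set(taxon_labels)
            if unknown:
                raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
            if tree.leaf_set != set(taxon_labels):
                missing = sorted(set(taxon_labels) - tree.leaf_set)
                raise ValueError(f"tree is missing taxa: {missing}")
        out.append(tree)
    return out


def write_trees(trees: Iterable[PhyloTree], path: Union[str, os.PathLike]) -> None:
    Path(path).write_text("".join(t.to_newick() + "\n" for t in trees))


# ---------------------------------------------------------------------------
# Tables and heatmaps
# ---------------------------------------------------------------------------

def write_table(dist, path: Union[str, os.PathLike], format: str = "csv") -> Path:
    """Write a labelled square distance matrix as CSV or an SVG heatmap.

    ``dist`` is any object with ``labels`` (sequence) and ``values`` (square
    array with entries in [0, 1]), e.g. :class:`depclad.tree_compare.DistanceMatrix`.
    """
    values = np.asarray(dist.values, dtype=float)
    labels = list(dist.labels)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(labels) != values.shape[0]:
        raise ValueError("label count does not match matrix size")
    path = Path(path)
    if format == "csv":
        pd.DataFrame(values, index=labels, columns=labels).to_csv(path)
    elif format == "svg-heatmap":
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.3 * len(labels)), max(3.5, 0.3 * len(labels)))
        )
        im = ax.imshow(values, vmin=0.0, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
        fig.colorbar(im, ax=ax, label="nRF distance")
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError(f"unknown table format {format!r}")
    return path
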