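"""NEXUS I/O for character-taxon matrices of unordered multistate
morphological characters.

Cells are state sets: a singleton for an ordinary observation, a larger
set for a polymorphic/ambiguous cell, or one of the two sentinels
:data:`MISSING` (``?``) and :data:`INAPPLICABLE` (``-``).  The two
sentinels round-trip distinctly but are treated identically by the
parsimony engine, the standard practice for unordered Fitch optimization.

Character indices are 1-based in every user-facing API and report so that
character numbers cross-reference published synapomorphy lists directly;
internal storage is 0-based and never leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import dendropy

MISSING = "?"
INAPPLICABLE = "-"

#: A matrix cell: a frozenset of state symbols, or a sentinel string.
Cell = Union[frozenset, str]


class NexusFormatError(ValueError):
    """Malformed or inconsistent NEXUS character data."""


@dataclass
class CharacterMatrix:
    """Taxa x unordered multistate characters with missing/polymorphic cells.

    All characters are assumed unordered with weight 1.  State symbols are
    the digits ``0``-``9``.
    """

    taxa: list[str]
    cells: list[list[Cell]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.cells):
            raise NexusFormatError("one row of cells per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise NexusFormatError(f"duplicate taxon names: {dupes}")
        if not self.cells or not self.cells[0]:
            raise NexusFormatError("matrix must contain at least one character")
        width = len(self.cells[0])
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != width:
                raise NexusFormatError(
                    f"row for {taxon!r} has {len(row)} cells, expected {width}"
                )
            for cell in row:
                if isinstance(cell, frozenset):
                    bad = [s for s in cell if s not in "0123456789"]
                    if bad or not cell:
                        raise NexusFormatError(
                            f"invalid state symbols {bad} for taxon {taxon!r}"
                        )
                elif cell not in (MISSING, INAPPLICABLE):
                    raise NexusFormatError(f"invalid cell {cell!r} for {taxon!r}")

    # -- dimensions --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0])

    # -- access (1-based character coordinates) ---------------------------

    def _taxon_row(self, taxon: str) -> list[Cell]:
        try:
            return self.cells[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def cell(self, taxon: str, char: int) -> Cell:
        if not 1 <= char <= self.n_char:
            raise IndexError(f"character index {char} out of range 1..{self.n_char}")
        return self._taxon_row(taxon)[char - 1]

    def column(self, char: int) -> list[Cell]:
        """State sets of character ``char`` (1-based), aligned with ``taxa``."""
        if not 1 <= char <= self.n_char:
            raise IndexError(f"character index {char} out of range 1..{self.n_char}")
        return [row[char - 1] for row in self.cells]

    def row(self, taxon: str) -> list[Cell]:
        return list(self._taxon_row(taxon))

    def symbols(self) -> str:
        used: set[str] = set()
        for row in self.cells:
            for cell in row:
                if isinstance(cell, frozenset):
                    used |= cell
        return "".join(sorted(used)) or "01"

    # -- export ------------------------------------------------------------

    def to_tsv(self) -> str:
        """Plain TSV rendering of the matrix for inspection."""
        lines = ["taxon\t" + "\t".join(str(i + 1) for i in range(self.n_char))]
        for taxon, row in zip(self.taxa, self.cells):
            lines.append(taxon + "\t" + "\t".join(_format_cell(c) for c in row))
        return "\n".join(lines) + "\n"


def _format_cell(cell: Cell) -> str:
    if cell == MISSING:
        return MISSING
    if cell == INAPPLICABLE:
        return INAPPLICABLE
    states = sorted(cell)
    if len(states) == 1:
        return states[0]
    return "{" + "".join(states) + "}"


# -- reading ----------------------------------------------------------------


def read_nexus_matrix(text: str) -> CharacterMatrix:
    """Parse a NEXUS document with a DATA or CHARACTERS block.

    Both Mesquite- and TNT-exported NEXUS dialects parse (standard blocks;
    FORMAT SYMBOLS, MISSING, GAP and INTERLEAVE are honored).  ``?`` maps
    to :data:`MISSING`, ``-`` to :data:`INAPPLICABLE`, and ``{..}`` /
    ``(..)`` tokens to polymorphic state sets.  Declared and parsed
    dimensions must agree or a descriptive error is raised.
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True)
    except Exception as exc:
        raise NexusFormatError(f"NEXUS parse error: {exc}") from None
    if len(dmat) == 0:
        raise NexusFormatError("no character rows found in NEXUS input")

    taxa: list[str] = []
    cells: list[list[Cell]] = []
    for taxon in dmat:
        taxa.append(taxon.label)
        row: list[Cell] = []
        for sid in dmat[taxon]:
            row.append(_convert_state(sid, taxon.label))
        cells.append(row)
    widths = {len(r) for r in cells}
    if len(widths) != 1:
        raise NexusFormatError(f"unequal row lengths parsed: {sorted(widths)}")
    return CharacterMatrix(taxa, cells)


def _convert_state(sid, taxon: str) -> Cell:
    sym = sid.symbol
    if sym == "?":
        return MISSING
    if sym == "-":
        return INAPPLICABLE
    alphabet = dendropy.datamodel.charstatemodel.StateAlphabet
    if sid.state_denomination == alphabet.FUNDAMENTAL_STATE:
        return frozenset([sym])
    members = {
        m.symbol
        for m in sid.member_states
        if m.symbol is not None and m.symbol not in ("?", "-")
    }
    if not members:
        return MISSING
    return frozenset(members)


def read_nexus_file(path) -> CharacterMatrix:
    with open(path) as fh:
        return read_nexus_matrix(fh.read())


# -- writing ----------------------------------------------------------------


def write_nexus_matrix(m: CharacterMatrix) -> str:
    """Emit a standard NEXUS document (DATA block) that re-reads identically.

    Polymorphic cells are written in curly braces (``{01}``); missing and
    inapplicable cells as ``?`` and ``-``.
    """
    name_w = max(len(_quote_taxon(t)) for t in m.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_char};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{m.symbols()}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for taxon, row in zip(m.taxa, m.cells):
        body = "".join(_format_cell(c) for c in row)
        lines.append(f"        {_quote_taxon(taxon):<{name_w}}{body}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def _quote_taxon(name: str) -> str:
    if any(ch in " (){}[];," for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_nexus_file(m: CharacterMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_nexus_matrix(m))
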