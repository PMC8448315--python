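"""Morphological character matrices: I/O, recoding, filtering, partitioning.

A :class:`CharacterMatrix` holds taxa x discrete characters.  Cells are stored
as *tokens*: after :func:`recode_for_analysis` every token is a single symbol
from ``{0..9, ?, -}``, but freshly read matrices may still carry polymorphism
notation (``(01)``, ``{01}``, ``0/1``) and letter states — recoding those to
missing is an explicit, reported step, mirroring how published phenomic
matrices are prepared for analysis.

``?`` (missing) and ``-`` (inapplicable) are preserved as distinct symbols in
storage; downstream parsimony treats both as the universal state set, but the
inapplicability repair in :mod:`pseudoext.ancestors` needs the distinction.

Character indices are 1-based in every user-facing report and file, following
the convention of published character lists.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "CharacterMatrix",
    "CharacterPartition",
    "DependencyMap",
    "MatrixParseError",
    "RecodeReport",
    "read_matrix",
    "write_matrix",
    "recode_for_analysis",
    "remove_constant_characters",
    "apply_pseudoextinction_coding",
]

STATE_SYMBOLS = set("0123456789")
SPECIAL_SYMBOLS = {"?", "-"}
ANALYSIS_ALPHABET = STATE_SYMBOLS | SPECIAL_SYMBOLS


class MatrixParseError(ValueError):
    """Malformed matrix file (names the offending line or taxon)."""


@dataclass(frozen=True)
class CharacterPartition:
    """Disjoint 1-based index sets covering all characters of a matrix."""

    osteological: frozenset[int]
    non_osteological: frozenset[int]

    def validate(self, n_char: int) -> None:
        if self.osteological & self.non_osteological:
            raise ValueError("partition sets overlap")
        if self.osteological | self.non_osteological != frozenset(range(1, n_char + 1)):
            raise ValueError(
                f"partition does not cover characters 1..{n_char} exactly"
            )

    @classmethod
    def from_osteological(cls, osteological: Iterable[int], n_char: int
                          ) -> "CharacterPartition":
        osteo = frozenset(osteological)
        part = cls(osteo, frozenset(range(1, n_char + 1)) - osteo)
        part.validate(n_char)
        return part


@dataclass(frozen=True)
class DependencyMap:
    """Character dependencies: (controller, trigger states, dependent).

    A dependent character is inapplicable whenever its controller takes one of
    the trigger states.  Used by the ancestral-row repair step.
    """

    entries: tuple[tuple[int, frozenset[str], int], ...] = ()

    def validate(self, n_char: Optional[int] = None) -> None:
        for ctrl, trig, dep in self.entries:
            if ctrl == dep:
                raise ValueError(f"character {ctrl} depends on itself")
            if n_char is not None:
                for idx in (ctrl, dep):
                    if not 1 <= idx <= n_char:
                        raise ValueError(f"dependency index {idx} out of range 1..{n_char}")
            if not trig:
                raise ValueError(f"empty trigger set for controller {ctrl}")

    @classmethod
    def from_yaml(cls, path: str) -> "DependencyMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        entries = tuple(
            (int(e["controller"]), frozenset(str(s) for s in e["trigger_states"]),
             int(e["dependent"]))
            for e in raw
        )
        dm = cls(entries)
        dm.validate()
        return dm


class CharacterMatrix:
    """Taxa x characters with tokens over the analysis alphabet (plus raw
    polymorphism/letter tokens before recoding)."""

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence[str]],
        partition: Optional[CharacterPartition] = None,
        metadata: Optional[dict] = None,
    ):
        self.taxa = list(taxa)
        self.cells = [list(row) for row in cells]
        self.partition = partition
        self.metadata = dict(metadata or {})
        self._validate()

    def _validate(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixParseError(f"duplicate taxa: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise MatrixParseError("row count does not match taxon count")
        lengths = {len(row) for row in self.cells}
        if len(lengths) > 1:
            bad = [t for t, row in zip(self.taxa, self.cells)
                   if len(row) != len(self.cells[0])]
            raise MatrixParseError(
                f"ragged rows: taxa {bad} differ in character count"
            )
        if self.partition is not None:
            self.partition.validate(self.n_char)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon: str) -> list[str]:
        return self.cells[self.taxa.index(taxon)]

    def column(self, index: int) -> list[str]:
        """1-based character column."""
        return [row[index - 1] for row in self.cells]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(self.taxa, self.cells, self.partition,
                               self.metadata)

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ValueError(f"unknown taxa: {missing}")
        return CharacterMatrix(
            list(taxa), [self.cells[index[t]] for t in taxa],
            self.partition, self.metadata,
        )

    def add_rows(self, taxa: Sequence[str], cells: Sequence[Sequence[str]]
                 ) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa + list(taxa),
            self.cells + [list(r) for r in cells],
            self.partition, self.metadata,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.cells == other.cells
            and self.partition == other.partition
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_char} characters)"


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_POLY_OPEN = {"(": ")", "{": "}"}


def tokenize_row(text: str, taxon: str, strict: bool = False) -> list[str]:
    """Split a state string into cell tokens.

    Accepts digits, ``?``, ``-``, letter states, and polymorphism groups
    ``(..)``, ``{..}`` and ``a/b``.  Unknown symbols become ``?`` with a
    warning unless ``strict``.
    """
    tokens: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in _POLY_OPEN:
            close = _POLY_OPEN[ch]
            j = text.find(close, i + 1)
            if j < 0:
                raise MatrixParseError(
                    f"taxon {taxon!r}: unclosed polymorphism group at column {i + 1}"
                )
            tokens.append(text[i:j + 1])
            i = j + 1
        elif ch.isspace():
            i += 1
        elif i + 2 <= n - 1 and text[i + 1] == "/" and not ch.isspace():
            # slash polymorphism: a/b (possibly a/b/c)
            j = i
            parts = [ch]
            while j + 2 < n and text[j + 1] == "/":
                parts.append(text[j + 2])
                j += 2
            tokens.append("/".join(parts))
            i = j + 1
        elif ch in ANALYSIS_ALPHABET or ch.isalpha():
            tokens.append(ch)
            i += 1
        else:
            if strict:
                raise MatrixParseError(
                    f"taxon {taxon!r}: unknown symbol {ch!r} at column {i + 1}"
                )
            warnings.warn(
                f"taxon {taxon!r}: unknown symbol {ch!r} recoded to '?'",
                stacklevel=2,
            )
            tokens.append("?")
            i += 1
    return tokens


def _token_to_text(token: str) -> str:
    return token


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_charset_ranges(text: str) -> frozenset[int]:
    out: set[int] = set()
    for part in text.replace(",", " ").split():
        if "-" in part[1:]:
            lo, hi = part.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return frozenset(out)


def _strip_nexus_comments(text: str) -> str:
    return re.sub(r"\[[^\]]*\]", "", text)


def _read_nexus(text: str, strict: bool) -> tuple[list[str], list[list[str]],
                                                  Optional[frozenset[int]]]:
    body = _strip_nexus_comments(text)
    m = re.search(r"\bMATRIX\b(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixParseError("no MATRIX statement found in NEXUS file")
    taxa: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(m.group(1).splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            j = line.index("'", 1)
            taxon, states = line[1:j], line[j + 1:]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise MatrixParseError(
                    f"MATRIX line {lineno}: expected 'taxon states', got {line!r}"
                )
            taxon, states = parts
        if taxon in taxa:
            raise MatrixParseError(f"duplicate taxon {taxon!r} in MATRIX")
        taxa.append(taxon)
        rows.append(tokenize_row(states.strip(), taxon, strict))
    mdim = re.search(r"\bNCHAR\s*=\s*(\d+)", body, re.IGNORECASE)
    if mdim:
        nchar = int(mdim.group(1))
        for taxon, row in zip(taxa, rows):
            if len(row) != nchar:
                raise MatrixParseError(
                    f"taxon {taxon!r}: {len(row)} symbols, NCHAR={nchar}"
                )
    mcs = re.search(r"\bCHARSET\s+osteological\s*=\s*([^;]+);", body,
                    re.IGNORECASE)
    osteo = _parse_charset_ranges(mcs.group(1)) if mcs else None
    return taxa, rows, osteo


def _read_tnt(text: str, strict: bool) -> tuple[list[str], list[list[str]], None]:
    body = re.sub(r"(\bxread\b\s*)'[^']*'", r"\1", text)  # optional title
    m = re.search(r"\bxread\b(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixParseError("no xread statement found in TNT file")
    content = m.group(1).strip()
    header = content.split(None, 2)
    if len(header) < 3:
        raise MatrixParseError("xread header must give nchar and ntax")
    try:
        nchar, ntax = int(header[0]), int(header[1])
    except ValueError as exc:
        raise MatrixParseError(f"bad xread header: {exc}") from exc
    taxa: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(content.split(None, 2)[2].splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            j = line.index("'", 1)
            taxon, states = line[1:j], line[j + 1:]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise MatrixParseError(
                    f"xread line {lineno}: expected 'taxon states', got {line!r}"
                )
            taxon, states = parts
        if taxon in taxa:
            raise MatrixParseError(f"duplicate taxon {taxon!r} in xread")
        taxa.append(taxon)
        row = tokenize_row(states.strip(), taxon, strict)
        if len(row) != nchar:
            raise MatrixParseError(
                f"taxon {taxon!r}: {len(row)} symbols, header says {nchar}"
            )
        rows.append(row)
    if len(taxa) != ntax:
        raise MatrixParseError(f"{len(taxa)} taxa read, header says {ntax}")
    return taxa, rows, None


def _read_table(text: str, strict: bool) -> tuple[list[str], list[list[str]], None]:
    taxa: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise MatrixParseError(f"line {lineno}: expected 'taxon<TAB>states'")
        taxon, states = line.split("\t", 1)
        if taxon in taxa:
            raise MatrixParseError(f"duplicate taxon {taxon!r} at line {lineno}")
        taxa.append(taxon)
        rows.append(tokenize_row(states.strip(), taxon, strict))
    return taxa, rows, None


def _sidecar_path(path: str) -> str:
    return str(path) + ".charsets.yaml"


def read_matrix(path: str, dialect: str, strict: bool = False) -> CharacterMatrix:
    """Read a character matrix in the named dialect (nexus | tnt | table).

    The returned matrix may still contain polymorphism tokens and letter
    states; :func:`recode_for_analysis` is the separate, reported step that
    maps those to missing.
    """
    with open(path) as fh:
        text = fh.read()
    readers = {"nexus": _read_nexus, "tnt": _read_tnt, "table": _read_table}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(readers)}")
    taxa, rows, osteo = readers[dialect](text, strict)
    if not taxa:
        raise MatrixParseError("no taxon rows found")
    partition = None
    if osteo is None:
        import os

        if os.path.exists(_sidecar_path(path)):
            with open(_sidecar_path(path)) as fh:
                raw = yaml.safe_load(fh)
            osteo = frozenset(
                i for lo, hi in raw["osteological"] for i in range(lo, hi + 1)
            )
    if osteo is not None:
        partition = CharacterPartition.from_osteological(osteo, len(rows[0]))
    return CharacterMatrix(taxa, rows, partition,
                           metadata={"source": str(path), "dialect": dialect})


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _index_ranges(indices: frozenset[int]) -> str:
    """Compact 1-based range notation, e.g. '1-5 8 10-12'."""
    parts: list[str] = []
    run: list[int] = []
    for i in sorted(indices):
        if run and i == run[-1] + 1:
            run.append(i)
        else:
            if run:
                parts.append(str(run[0]) if len(run) == 1 else f"{run[0]}-{run[-1]}")
            run = [i]
    if run:
        parts.append(str(run[0]) if len(run) == 1 else f"{run[0]}-{run[-1]}")
    return " ".join(parts)


def _row_text(row: Sequence[str]) -> str:
    return "".join(_token_to_text(tok) for tok in row)


def _taxon_field(taxon: str) -> str:
    if re.search(r"\s", taxon):
        return f"'{taxon}'"
    return taxon


def write_matrix(m: CharacterMatrix, path: str, dialect: str) -> None:
    """Write a matrix; guaranteed to round-trip through :func:`read_matrix`.

    NEXUS output embeds the partition as a SETS block; TNT and table dialects
    write a YAML sidecar next to the file.
    """
    width = max(len(_taxon_field(t)) for t in m.taxa) + 2
    lines: list[str] = []
    if dialect == "nexus":
        lines.append("#NEXUS")
        lines.append("BEGIN DATA;")
        lines.append(f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_char};")
        lines.append('    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;')
        lines.append("    MATRIX")
        for taxon, row in zip(m.taxa, m.cells):
            lines.append(f"        {_taxon_field(taxon):<{width}}{_row_text(row)}")
        lines.append("    ;")
        lines.append("END;")
        if m.partition is not None:
            lines.append("BEGIN SETS;")
            lines.append(
                f"    CHARSET osteological = {_index_ranges(m.partition.osteological)};"
            )
            lines.append("END;")
    elif dialect == "tnt":
        lines.append("xread")
        lines.append(f"{m.n_char} {m.n_taxa}")
        for taxon, row in zip(m.taxa, m.cells):
            lines.append(f"{_taxon_field(taxon):<{width}}{_row_text(row)}")
        lines.append(";")
    elif dialect == "table":
        for taxon, row in zip(m.taxa, m.cells):
            lines.append(f"{taxon}\t{_row_text(row)}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if dialect in ("tnt", "table") and m.partition is not None:
        runs = _index_ranges(m.partition.osteological).split()
        ranges = []
        for r in runs:
            if "-" in r[1:]:
                lo, hi = r.split("-", 1)
                ranges.append([int(lo), int(hi)])
            else:
                ranges.append([int(r), int(r)])
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump({"osteological": ranges}, fh)


# ---------------------------------------------------------------------------
# Recoding and filtering
# ---------------------------------------------------------------------------

@dataclass
class RecodeReport:
    """What :func:`recode_for_analysis` changed."""

    polymorphic_cells: int = 0
    letter_cells: int = 0
    unknown_cells: int = 0
    affected_characters: set[int] = field(default_factory=set)
    letter_characters: set[int] = field(default_factory=set)

    @property
    def cells_affected(self) -> int:
        return self.polymorphic_cells + self.letter_cells + self.unknown_cells


def recode_for_analysis(m: CharacterMatrix) -> tuple[CharacterMatrix, RecodeReport]:
    """Map every polymorphic scoring and every non-digit state to ``?``.

    After this step the symbol alphabet is exactly ``{0..9, ?, -}``.  The
    report carries cell and character counts, and separately the characters
    that had letter states, so holders of the source data can verify them.
    """
    report = RecodeReport()
    new_cells: list[list[str]] = []
    for row in m.cells:
        new_row: list[str] = []
        for j, tok in enumerate(row, start=1):
            if len(tok) > 1:  # (..), {..}, a/b polymorphism
                report.polymorphic_cells += 1
                report.affected_characters.add(j)
                new_row.append("?")
            elif tok in ANALYSIS_ALPHABET:
                new_row.append(tok)
            elif tok.isalpha():
                report.letter_cells += 1
                report.affected_characters.add(j)
                report.letter_characters.add(j)
                new_row.append("?")
            else:
                report.unknown_cells += 1
                report.affected_characters.add(j)
                new_row.append("?")
    # re-attach rows
        new_cells.append(new_row)
    return (
        CharacterMatrix(m.taxa, new_cells, m.partition, m.metadata),
        report,
    )


def remove_constant_characters(m: CharacterMatrix
                               ) -> tuple[CharacterMatrix, list[int]]:
    """Drop characters with at most one observed state (ignoring ``?``/``-``).

    Returns the filtered matrix (partition indices remapped) and the 1-based
    indices of the removed characters.
    """
    removed: list[int] = []
    kept: list[int] = []
    for j in range(1, m.n_char + 1):
        observed = {tok for tok in m.column(j) if tok not in SPECIAL_SYMBOLS}
        if len(observed) <= 1:
            removed.append(j)
        else:
            kept.append(j)
    new_cells = [[row[j - 1] for j in kept] for row in m.cells]
    partition = None
    if m.partition is not None:
        old_to_new = {old: new for new, old in enumerate(kept, start=1)}
        osteo = frozenset(
            old_to_new[j] for j in m.partition.osteological if j in old_to_new
        )
        partition = CharacterPartition.from_osteological(osteo, len(kept))
    return CharacterMatrix(m.taxa, new_cells, partition, m.metadata), removed


def apply_pseudoextinction_coding(m: CharacterMatrix,
                                  focal_taxa: Iterable[str]) -> CharacterMatrix:
    """Score every non-osteological character as ``?`` for the focal taxa.

    This is the pseudoextinction operation: soft-tissue and behavioral
    characters are unknowable for extinct taxa, so a pseudoextinct taxon keeps
    only its osteological scorings.  Idempotent; other taxa untouched.
    """
    focal = set(focal_taxa)
    if not focal:
        return m.copy()
    unknown = focal - set(m.taxa)
    if unknown:
        raise ValueError(f"unknown focal taxa: {sorted(unknown)}")
    if m.partition is None:
        raise ValueError("matrix has no character partition")
    soft = m.partition.non_osteological
    new_cells = []
    for taxon, row in zip(m.taxa, m.cells):
        if taxon in focal:
            new_cells.append(
                ["?" if (j in soft) else tok for j, tok in enumerate(row, 1)]
            )
        else:
            new_cells.append(list(row))
    return CharacterMatrix(m.taxa, new_cells, m.partition, m.metadata)
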