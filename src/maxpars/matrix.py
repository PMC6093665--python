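"""Discrete morphological character matrices: TNT and NEXUS dialects.

The in-memory model is a taxa x characters grid of state sets over the
integer alphabet 0-9.  ``?`` and ``-`` are both treated as fully missing
(the usual convention for discrete morphology, where gaps carry no separate
meaning); polymorphic cells hold two or more states.  A per-character flag
marks additive (ordered) characters, in which a change from state i to j
costs |i-j| instead of 1.

Parsing covers the TNT ``xread`` block (with a ``ccode`` additivity
declaration, 0-based character numbers as in TNT) and a NEXUS DATA /
CHARACTERS block (with an ASSUMPTIONS TYPESET naming ``ord`` characters,
1-based as in NEXUS).  All user-facing character indices — scoring edits,
reports — are 1-based; only the TNT ccode line uses TNT's own 0-based
numbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "StateSet", "CharacterMatrix", "ScoringEdit", "MatrixParseError",
    "MISSING", "parse_matrix", "write_matrix", "merge_otus",
    "apply_scoring_edits",
]

MAX_STATE = 9


class MatrixParseError(ValueError):
    """Raised when a matrix file violates its declared structure."""


@dataclass(frozen=True)
class StateSet:
    """The states a taxon may exhibit for one character.

    A missing cell ('?' or '-') is maximally ambiguous: it is compatible
    with every state of its character and never adds parsimony cost.
    """

    states: frozenset[int] = frozenset()
    is_missing: bool = False

    def __post_init__(self):
        if self.is_missing:
            if self.states:
                raise ValueError("missing cell must carry no explicit states")
        else:
            if not self.states:
                raise ValueError("non-missing cell must be non-empty")
            if not all(0 <= s <= MAX_STATE for s in self.states):
                raise ValueError(f"states outside 0..{MAX_STATE}: {set(self.states)}")

    @classmethod
    def of(cls, *states: int) -> "StateSet":
        return cls(frozenset(states))

    @property
    def is_polymorphic(self) -> bool:
        return len(self.states) >= 2

    def __str__(self) -> str:
        if self.is_missing:
            return "?"
        if self.is_polymorphic:
            return "[" + "".join(str(s) for s in sorted(self.states)) + "]"
        return str(next(iter(self.states)))


MISSING = StateSet(is_missing=True)


def normalize_label(label: str) -> str:
    """TNT writes spaces as underscores; compare labels modulo that."""
    return re.sub(r"[\s_]+", " ", label).strip()


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of :class:`StateSet` with additivity flags."""

    taxa: list[str]
    cells: list[list[StateSet]]
    ordered: list[bool] = field(default_factory=list)
    title: str = ""

    def __post_init__(self):
        if len(self.taxa) != len(self.cells):
            raise ValueError("one row of cells per taxon required")
        norm = [normalize_label(t) for t in self.taxa]
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate taxon labels")
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise ValueError(f"ragged rows: widths {sorted(widths)}")
        if not self.ordered:
            self.ordered = [False] * self.nchar
        if len(self.ordered) != self.nchar:
            raise ValueError("one ordered flag per character required")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def taxon_index(self, label: str) -> int:
        want = normalize_label(label)
        for i, t in enumerate(self.taxa):
            if normalize_label(t) == want:
                return i
        raise KeyError(f"taxon {label!r} not in matrix")

    def row(self, label: str) -> list[StateSet]:
        return self.cells[self.taxon_index(label)]

    def column(self, j: int) -> dict[str, StateSet]:
        """0-based column as a taxon->cell mapping."""
        return {t: self.cells[i][j] for i, t in enumerate(self.taxa)}

    def max_state(self, j: int) -> int:
        """Largest observed state index of character ``j`` (0-based)."""
        best = 0
        for row in self.cells:
            if not row[j].is_missing:
                best = max(best, max(row[j].states))
        return best

    @property
    def alphabet_per_char(self) -> list[int]:
        return [self.max_state(j) for j in range(self.nchar)]

    def drop_taxa(self, labels: list[str]) -> "CharacterMatrix":
        idx = {self.taxon_index(lab) for lab in labels}
        return CharacterMatrix(
            taxa=[t for i, t in enumerate(self.taxa) if i not in idx],
            cells=[r for i, r in enumerate(self.cells) if i not in idx],
            ordered=list(self.ordered), title=self.title)

    def concat(self, other: "CharacterMatrix") -> "CharacterMatrix":
        """Append the characters of a second matrix over the same taxa."""
        if {normalize_label(t) for t in self.taxa} != \
           {normalize_label(t) for t in other.taxa}:
            raise ValueError("taxon sets differ")
        cells = [row + other.row(t) for t, row in zip(self.taxa, self.cells)]
        return CharacterMatrix(list(self.taxa), cells,
                               list(self.ordered) + list(other.ordered))

    def equals(self, other: "CharacterMatrix") -> bool:
        """Equality modulo whitespace/underscore label normalization."""
        if self.ordered != other.ordered:
            return False
        mine = {normalize_label(t): r for t, r in zip(self.taxa, self.cells)}
        theirs = {normalize_label(t): r for t, r in zip(other.taxa, other.cells)}
        return mine == theirs


@dataclass(frozen=True)
class ScoringEdit:
    """One cell re-scoring, addressed the way such edits are printed:
    ``taxon, character (1-based): old -> new``. ``old=None`` asserts the cell
    was previously unknown/unchecked; ``new=None`` sets the cell missing."""

    taxon: str
    char: int                    # 1-based, as printed
    new: int | None
    old: int | None = None
    check_old: bool = False


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"\[([0-9]+)\]|\{([0-9]+)\}|\(([0-9]+)\)|([0-9?\-])")


def _parse_state_string(text: str, where: str) -> list[StateSet]:
    cells = []
    pos = 0
    while pos < len(text):
        m = _CELL_RE.match(text, pos)
        if not m:
            raise MatrixParseError(
                f"illegal state symbol {text[pos]!r} at column {pos + 1} in {where}")
        pos = m.end()
        multi = m.group(1) or m.group(2) or m.group(3)
        if multi is not None:
            cells.append(StateSet(frozenset(int(c) for c in multi)))
        elif m.group(4) in "?-":
            cells.append(MISSING)
        else:
            cells.append(StateSet.of(int(m.group(4))))
    return cells


def _expand_index_tokens(tokens: list[str], where: str) -> list[int]:
    out = []
    for tok in tokens:
        m = re.fullmatch(r"(\d+)(?:[.\-](\d+))?", tok)
        if not m:
            raise MatrixParseError(f"bad character index {tok!r} in {where}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        out.extend(range(lo, hi + 1))
    return out


def _strip_nexus_comments(text: str) -> str:
    return re.sub(r"\[(?![0-9]+\])[^\]]*\]", " ", text)


def _parse_tnt(text: str) -> CharacterMatrix:
    m = re.search(r"\bxread\b", text, re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread block found")
    rest = text[m.end():]
    title = ""
    tm = re.match(r"\s*'([^']*)'", rest, re.DOTALL)
    if tm:
        title = tm.group(1).strip()
        rest = rest[tm.end():]
    hm = re.match(r"\s*(\d+)\s+(\d+)", rest)
    if not hm:
        raise MatrixParseError("xread header must declare 'nchar ntax'")
    nchar, ntax = int(hm.group(1)), int(hm.group(2))
    rest = rest[hm.end():]
    end = rest.find(";")
    if end < 0:
        raise MatrixParseError("xread block not terminated by ';'")
    body, tail = rest[:end], rest[end + 1:]

    tokens = body.split()
    taxa, rows = [], []
    i = 0
    for _ in range(ntax):
        if i >= len(tokens):
            raise MatrixParseError(
                f"expected {ntax} taxa, found only {len(taxa)}")
        label = tokens[i]
        i += 1
        cells: list[StateSet] = []
        while len(cells) < nchar:
            if i >= len(tokens):
                raise MatrixParseError(
                    f"row for taxon {label!r} has {len(cells)} cells, "
                    f"expected {nchar}")
            cells.extend(_parse_state_string(tokens[i], f"row {label!r}"))
            i += 1
        if len(cells) != nchar:
            raise MatrixParseError(
                f"row for taxon {label!r} has {len(cells)} cells, "
                f"expected {nchar}")
        taxa.append(label)
        rows.append(cells)
    if i < len(tokens):
        raise MatrixParseError(
            f"{len(tokens) - i} unexpected tokens after row {taxa[-1]!r} "
            f"(declared ntax={ntax})")

    ordered = [False] * nchar
    saw_ccode = False
    for cm in re.finditer(r"\bccode\b([^;]*);", tail, re.IGNORECASE):
        saw_ccode = True
        mode = None
        for tok in cm.group(1).split():
            if tok in "+-":
                mode = tok
            elif tok[0] in "+-" and len(tok) > 1:
                mode = tok[0]
                for j in _expand_index_tokens([tok[1:]], "ccode"):
                    _set_ordered(ordered, j, mode == "+", base=0)
            else:
                if mode is None:
                    raise MatrixParseError(f"ccode token {tok!r} before any +/-")
                for j in _expand_index_tokens([tok], "ccode"):
                    _set_ordered(ordered, j, mode == "+", base=0)
    if not saw_ccode:
        logger.warning("no ccode declaration found; all characters "
                       "treated as unordered (non-additive)")
    return CharacterMatrix(taxa, rows, ordered, title)


def _set_ordered(flags: list[bool], idx: int, value: bool, base: int) -> None:
    j = idx - base
    if not 0 <= j < len(flags):
        raise MatrixParseError(
            f"character number {idx} outside 1..{len(flags)}"
            if base else f"character number {idx} outside 0..{len(flags) - 1}")
    flags[j] = value


def _parse_nexus(text: str) -> CharacterMatrix:
    text = _strip_nexus_comments(text)
    bm = re.search(
        r"begin\s+(?:data|characters)\s*;(.*?)end\s*;", text,
        re.IGNORECASE | re.DOTALL)
    if not bm:
        raise MatrixParseError("no DATA/CHARACTERS block found")
    block = bm.group(1)
    dm = re.search(r"dimensions\b([^;]*);", block, re.IGNORECASE)
    if not dm:
        raise MatrixParseError("missing DIMENSIONS command")
    dims = dict(re.findall(r"(ntax|nchar)\s*=\s*(\d+)", dm.group(1),
                           re.IGNORECASE))
    dims = {k.lower(): int(v) for k, v in dims.items()}
    if "ntax" not in dims or "nchar" not in dims:
        raise MatrixParseError("DIMENSIONS must give NTAX and NCHAR")
    ntax, nchar = dims["ntax"], dims["nchar"]

    mm = re.search(r"matrix\b(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mm:
        raise MatrixParseError("missing MATRIX command")
    taxa, rows = [], []
    for line in mm.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        lm = re.match(r"'([^']*)'\s*(.*)$|(\S+)\s+(.*)$", line)
        if not lm:
            raise MatrixParseError(f"unparseable matrix row: {line!r}")
        label = lm.group(1) if lm.group(1) is not None else lm.group(3)
        states = (lm.group(2) if lm.group(1) is not None else lm.group(4))
        cells = _parse_state_string(states.replace(" ", ""), f"row {label!r}")
        if len(cells) != nchar:
            raise MatrixParseError(
                f"row for taxon {label!r} has {len(cells)} cells, "
                f"expected {nchar}")
        taxa.append(label)
        rows.append(cells)
    if len(taxa) != ntax:
        raise MatrixParseError(f"found {len(taxa)} rows, declared NTAX={ntax}")

    ordered = [False] * nchar
    saw_typeset = False
    for tm in re.finditer(r"typeset\b[^;=]*=([^;]*);", text, re.IGNORECASE):
        saw_typeset = True
        for part in tm.group(1).split(","):
            pm = re.match(r"\s*(\w+)\s*:\s*(.*)$", part)
            if not pm:
                continue
            kind = pm.group(1).lower()
            if kind not in ("ord", "unord"):
                continue
            for j in _expand_index_tokens(pm.group(2).split(), "TYPESET"):
                _set_ordered(ordered, j, kind == "ord", base=1)
    if not saw_typeset:
        logger.warning("no TYPESET declaration found; all characters "
                       "treated as unordered (non-additive)")
    return CharacterMatrix(taxa, rows, ordered)


def parse_matrix(text: str, dialect: str = "auto") -> CharacterMatrix:
    """Parse a TNT xread or NEXUS character matrix from file content."""
    if dialect == "auto":
        stripped = text.lstrip()
        if stripped.upper().startswith("#NEXUS"):
            dialect = "nexus"
        elif re.search(r"\bxread\b", text, re.IGNORECASE):
            dialect = "tnt"
        else:
            raise MatrixParseError(
                "cannot identify dialect: neither '#NEXUS' nor 'xread' found")
    if dialect == "tnt":
        return _parse_tnt(text)
    if dialect == "nexus":
        return _parse_nexus(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _tnt_label(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def write_matrix(matrix: CharacterMatrix, dialect: str = "tnt") -> str:
    """Serialize a matrix; the output re-parses to an equal matrix."""
    if dialect == "tnt":
        width = max(len(_tnt_label(t)) for t in matrix.taxa)
        lines = ["xread", f"'{matrix.title or 'written by maxpars'}'",
                 f"{matrix.nchar} {matrix.ntax}"]
        for t, row in zip(matrix.taxa, matrix.cells):
            states = "".join(str(c) for c in row)
            lines.append(f"{_tnt_label(t):<{width}} {states}")
        lines.append(";")
        if any(matrix.ordered):
            idx = " ".join(str(j) for j, o in enumerate(matrix.ordered) if o)
            lines.append(f"ccode + {idx};")
        lines.append("proc /;")
        return "\n".join(lines) + "\n"
    if dialect == "nexus":
        def nex_cell(c: StateSet) -> str:
            if c.is_missing:
                return "?"
            if c.is_polymorphic:
                return "(" + "".join(str(s) for s in sorted(c.states)) + ")"
            return str(next(iter(c.states)))

        def nex_label(t: str) -> str:
            return "'" + t.replace("'", "''") + "'" if re.search(r"\s", t) else t

        sym = "".join(str(s) for s in range(max(matrix.alphabet_per_char, default=1) + 1))
        width = max(len(nex_label(t)) for t in matrix.taxa)
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
                 f"FORMAT DATATYPE=STANDARD SYMBOLS=\"{sym}\" MISSING=? GAP=-;",
                 "MATRIX"]
        for t, row in zip(matrix.taxa, matrix.cells):
            states = "".join(nex_cell(c) for c in row)
            lines.append(f"{nex_label(t):<{width}} {states}")
        lines.append(";")
        lines.append("END;")
        if any(matrix.ordered):
            idx = " ".join(str(j + 1) for j, o in enumerate(matrix.ordered) if o)
            lines += ["BEGIN ASSUMPTIONS;",
                      f"TYPESET * default = ord: {idx};",
                      "END;"]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------

def merge_otus(matrix: CharacterMatrix, source_label: str, target_label: str,
               conflict_policy: str = "union") -> CharacterMatrix:
    """Combine the scorings of two OTUs into the target row.

    Cell-wise rule: a known cell beats a missing one; two known cells with
    common states keep the intersection; two known, disjoint cells are a
    scoring conflict — under the ``union`` policy the union is kept and the
    conflict logged, under ``error`` the merge fails.
    """
    if conflict_policy not in ("union", "error"):
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    si = matrix.taxon_index(source_label)
    ti = matrix.taxon_index(target_label)
    if si == ti:
        raise ValueError("source and target are the same OTU")
    merged = []
    for j, (a, b) in enumerate(zip(matrix.cells[si], matrix.cells[ti])):
        if a.is_missing and b.is_missing:
            merged.append(MISSING)
        elif a.is_missing:
            merged.append(b)
        elif b.is_missing:
            merged.append(a)
        else:
            common = a.states & b.states
            if common:
                merged.append(StateSet(common))
            else:
                if conflict_policy == "error":
                    raise ValueError(
                        f"conflicting scorings at character {j + 1}: "
                        f"{a} vs {b}")
                logger.warning(
                    "merge conflict at character %d: %s vs %s -> union",
                    j + 1, a, b)
                merged.append(StateSet(a.states | b.states))
    taxa = [t for i, t in enumerate(matrix.taxa) if i != si]
    cells = [r for i, r in enumerate(matrix.cells) if i != si]
    cells[taxa.index(matrix.taxa[ti])] = merged
    return CharacterMatrix(taxa, cells, list(matrix.ordered), matrix.title)


def apply_scoring_edits(matrix: CharacterMatrix,
                        edits: list[ScoringEdit],
                        strict: bool = False) -> CharacterMatrix:
    """Apply cell re-scorings; old-state assertions are checked first.

    A mismatch between an edit's asserted old state and the current cell is
    logged (or raised, with ``strict=True``) before anything is applied.
    """
    mismatches = []
    for e in edits:
        if not 1 <= e.char <= matrix.nchar:
            raise IndexError(
                f"character {e.char} outside 1..{matrix.nchar}")
        i = matrix.taxon_index(e.taxon)
        if e.check_old:
            cell = matrix.cells[i][e.char - 1]
            expect = MISSING if e.old is None else StateSet.of(e.old)
            if cell != expect:
                mismatches.append(
                    f"{e.taxon} char {e.char}: expected {expect}, found {cell}")
    if mismatches:
        msg = "old-state assertions failed: " + "; ".join(mismatches)
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    cells = [list(row) for row in matrix.cells]
    for e in edits:
        i = matrix.taxon_index(e.taxon)
        cells[i][e.char - 1] = MISSING if e.new is None else StateSet.of(e.new)
    return CharacterMatrix(list(matrix.taxa), cells, list(matrix.ordered),
                           matrix.title)
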