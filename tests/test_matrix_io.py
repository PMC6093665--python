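"""Parsing, writing and editing of TNT/NEXUS character matrices."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxpars.matrix import (MISSING, CharacterMatrix, MatrixParseError,
                            ScoringEdit, StateSet, apply_scoring_edits,
                            merge_otus, parse_matrix, write_matrix)

TNT_EXAMPLE = """
xread
'four taxa, three characters'
3 4
Alpha_one  012
Beta       0[01]?
Gamma      1-2
Delta      ?22
;
ccode + 0 2;
proc /;
"""

NEXUS_EXAMPLE = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=3;
FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
MATRIX
Alpha_one  012
Beta       0(01)?
Gamma      1-2
Delta      ?22
;
END;
BEGIN ASSUMPTIONS;
TYPESET * default = ord: 1 3;
END;
"""


class TestParsing:
    @pytest.mark.parametrize("text,dialect", [
        (TNT_EXAMPLE, "tnt"), (NEXUS_EXAMPLE, "nexus"),
        (TNT_EXAMPLE, "auto"), (NEXUS_EXAMPLE, "auto"),
    ])
    def test_example_matrix(self, text, dialect):
        m = parse_matrix(text, dialect)
        assert (m.ntax, m.nchar) == (4, 3)
        assert m.taxa[0] == "Alpha_one"
        assert m.row("Beta")[1] == StateSet.of(0, 1)
        assert m.row("Beta")[2] == MISSING
        assert m.row("Gamma")[1] == MISSING          # '-' is fully missing
        assert m.ordered == [True, False, True]

    def test_smallest_legal_matrix(self):
        m = parse_matrix("xread '' 1 1\nonly ?\n;", "tnt")
        assert (m.ntax, m.nchar) == (1, 1)
        assert m.cells[0][0].is_missing

    def test_row_wrapped_over_lines(self):
        m = parse_matrix("xread '' 4 2\nA 01\n10\nB 0000\n;", "tnt")
        assert m.row("A") == [StateSet.of(0), StateSet.of(1),
                              StateSet.of(1), StateSet.of(0)]

    def test_dimension_mismatch_names_row(self):
        with pytest.raises(MatrixParseError, match="Beta"):
            parse_matrix("xread '' 3 2\nAlpha 012\nBeta 01\n;", "tnt")

    def test_bad_symbol_reports_position(self):
        with pytest.raises(MatrixParseError, match="column 2"):
            parse_matrix("xread '' 3 1\nAlpha 0x2\n;", "tnt")

    def test_missing_ordering_declaration_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            m = parse_matrix("xread '' 2 3\nA 01\nB 10\nC 11\n;", "tnt")
        assert m.ordered == [False, False]
        assert any("unordered" in r.message for r in caplog.records)

    def test_ccode_ranges(self):
        m = parse_matrix("xread '' 5 3\nA 01010\nB 10101\nC 11111\n;"
                         "\nccode + 1.3;", "tnt")
        assert m.ordered == [False, True, True, True, False]

    def test_unknown_dialect_rejected(self):
        with pytest.raises(MatrixParseError):
            parse_matrix("just some text", "auto")

    def test_nexus_agrees_with_dendropy(self):
        import dendropy
        dm = dendropy.StandardCharacterMatrix.get(data=NEXUS_EXAMPLE,
                                                  schema="nexus")
        m = parse_matrix(NEXUS_EXAMPLE, "nexus")
        assert len(dm) == m.ntax
        for taxon in dm:
            row = m.row(taxon.label)
            for j, dcell in enumerate(dm[taxon]):
                sym = str(dcell)
                if sym == "?":
                    assert row[j].is_missing
                elif sym.isdigit():
                    assert row[j] == StateSet.of(int(sym))


class TestWriting:
    def test_missing_written_as_question_mark(self):
        m = CharacterMatrix(["A", "B", "C"],
                            [[MISSING], [StateSet.of(1)], [StateSet.of(0)]])
        assert "?" in write_matrix(m, "tnt")

    def test_no_ordering_block_when_all_unordered(self):
        m = CharacterMatrix(["A", "B", "C"],
                            [[StateSet.of(0)], [StateSet.of(1)],
                             [StateSet.of(0)]])
        assert "ccode" not in write_matrix(m, "tnt")
        assert "TYPESET" not in write_matrix(m, "nexus")


@st.composite
def matrices(draw):
    n_taxa = draw(st.integers(2, 6))
    n_chars = draw(st.integers(1, 8))
    taxa = [f"tax{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            kind = draw(st.integers(0, 3))
            if kind == 0:
                row.append(MISSING)
            elif kind == 3:
                states = draw(st.sets(st.integers(0, 9), min_size=2,
                                      max_size=3))
                row.append(StateSet(frozenset(states)))
            else:
                row.append(StateSet.of(draw(st.integers(0, 9))))
        cells.append(row)
    ordered = [draw(st.booleans()) for _ in range(n_chars)]
    return CharacterMatrix(taxa, cells, ordered)


class TestRoundTrip:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(m=matrices(), dialect=st.sampled_from(["tnt", "nexus"]))
    def test_parse_write_identity(self, m, dialect):
        assert parse_matrix(write_matrix(m, dialect), dialect).equals(m)

    def test_bracket_cell_roundtrip(self):
        m = parse_matrix("xread '' 3 4\nA 0[01]1\nB 111\nC 0?0\nD -21\n;",
                         "tnt")
        assert m.row("A")[1] == StateSet.of(0, 1)
        assert parse_matrix(write_matrix(m, "tnt"), "tnt").equals(m)


class TestMergeOtus:
    def _pair_matrix(self, a, b):
        return CharacterMatrix(["S", "T", "X"], [[a], [b], [StateSet.of(0)]])

    def test_identical_rows_merge_unchanged(self):
        m = self._pair_matrix(StateSet.of(1), StateSet.of(1))
        out = merge_otus(m, "S", "T")
        assert out.ntax == m.ntax - 1
        assert out.row("T") == [StateSet.of(1)]

    def test_known_beats_unknown(self):
        out = merge_otus(self._pair_matrix(StateSet.of(0), MISSING), "S", "T")
        assert out.row("T") == [StateSet.of(0)]

    def test_all_two_state_cell_pairs(self, caplog):
        """Enumerate every pair of cells over states {0,1} (plus missing)
        against the stated rule."""
        universe = [MISSING, StateSet.of(0), StateSet.of(1), StateSet.of(0, 1)]
        for a in universe:
            for b in universe:
                with caplog.at_level(logging.WARNING):
                    caplog.clear()
                    out = merge_otus(self._pair_matrix(a, b), "S", "T")
                cell = out.row("T")[0]
                if a.is_missing and b.is_missing:
                    assert cell.is_missing
                elif a.is_missing or b.is_missing:
                    assert cell == (b if a.is_missing else a)
                elif a.states & b.states:
                    assert cell == StateSet(a.states & b.states)
                    assert not caplog.records
                else:
                    assert cell == StateSet(a.states | b.states)
                    assert len(caplog.records) == 1

    def test_conflict_under_error_policy(self):
        m = self._pair_matrix(StateSet.of(0), StateSet.of(1))
        with pytest.raises(ValueError, match="conflict"):
            merge_otus(m, "S", "T", conflict_policy="error")

    def test_merge_never_grows_cells_except_union(self, rng):
        from conftest import random_matrix
        m = random_matrix(rng, n_taxa=5, n_chars=10)
        out = merge_otus(m, m.taxa[0], m.taxa[1])
        for j, cell in enumerate(out.row(m.taxa[1])):
            a, b = m.cells[0][j], m.cells[1][j]
            if not (not a.is_missing and not b.is_missing
                    and not (a.states & b.states)):
                base = max(len(a.states), len(b.states))
                assert len(cell.states) <= max(base, 1) or cell.is_missing

    def test_unknown_label(self):
        m = self._pair_matrix(MISSING, MISSING)
        with pytest.raises(KeyError):
            merge_otus(m, "nope", "T")


class TestScoringEdits:
    def _matrix(self):
        return parse_matrix(
            "xread '' 5 2\nHolotype 00100\nOther 11111\n;", "tnt")

    def test_single_edit(self):
        out = apply_scoring_edits(self._matrix(),
                                  [ScoringEdit("Holotype", 4, new=1)])
        assert out.row("Holotype")[3] == StateSet.of(1)

    def test_empty_edit_list_is_identity(self):
        m = self._matrix()
        assert apply_scoring_edits(m, []).equals(m)

    def test_batch_of_rescorings(self):
        """Several 'char: old -> new' edits, including setting a cell to
        missing, land exactly where addressed."""
        edits = [ScoringEdit("Holotype", 1, new=1, old=0, check_old=True),
                 ScoringEdit("Holotype", 3, new=0, old=1, check_old=True),
                 ScoringEdit("Holotype", 5, new=None, old=0, check_old=True)]
        out = apply_scoring_edits(self._matrix(), edits)
        assert out.row("Holotype")[0] == StateSet.of(1)
        assert out.row("Holotype")[2] == StateSet.of(0)
        assert out.row("Holotype")[4].is_missing
        # unaddressed cells untouched
        assert out.row("Holotype")[1] == StateSet.of(0)
        assert out.row("Other") == self._matrix().row("Other")

    def test_old_state_mismatch_reported(self, caplog):
        edits = [ScoringEdit("Holotype", 1, new=1, old=1, check_old=True)]
        with caplog.at_level(logging.WARNING):
            apply_scoring_edits(self._matrix(), edits)
        assert any("assertion" in r.message for r in caplog.records)
        with pytest.raises(ValueError):
            apply_scoring_edits(self._matrix(), edits, strict=True)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            apply_scoring_edits(self._matrix(),
                                [ScoringEdit("Holotype", 6, new=0)])
        with pytest.raises(KeyError):
            apply_scoring_edits(self._matrix(),
                                [ScoringEdit("nobody", 1, new=0)])

    def test_label_matching_ignores_underscores(self):
        m = parse_matrix("xread '' 1 2\nBig_name 0\nOther 1\n;", "tnt")
        out = apply_scoring_edits(m, [ScoringEdit("Big name", 1, new=1)])
        assert out.row("Big_name")[0] == StateSet.of(1)
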