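"""Incidence-matrix data model, I/O and elementary operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestmax import (
    IncidenceMatrix,
    Ranking,
    degree_ranking,
    density,
    drop_empty,
    read_incidence,
    reorder,
    write_incidence,
)

from conftest import random_incidence


class TestIncidenceMatrix:
    def test_rejects_non_binary_entries(self):
        with pytest.raises(ValueError, match="0 or 1"):
            IncidenceMatrix.from_array([[2, 0], [0, 1]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            IncidenceMatrix([[1, 0], [0, 1]], ("a", "a"), ("x", "y"))

    def test_counts(self):
        m = IncidenceMatrix.from_array([[1, 1, 0], [0, 1, 0]])
        assert (m.n_rows, m.n_cols, m.n_links) == (2, 3, 3)
        assert m.fill == 0.5
        assert m.row_degrees.tolist() == [2, 1]
        assert m.col_degrees.tolist() == [1, 2, 0]


class TestRanking:
    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError, match="permutation"):
            Ranking(np.array([1, 1]), np.array([1, 2]))

    def test_permutation_lists_rank_one_first(self):
        r = Ranking(np.array([2, 1]), np.array([1, 2]))
        assert r.row_permutation.tolist() == [1, 0]


class TestDensity:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            (np.ones((3, 3)), 1.0),
            (np.zeros((3, 3)), 0.0),
        ],
    )
    def test_degenerate_fills(self, entries, expected):
        assert density(IncidenceMatrix.from_array(entries)) == expected

    def test_published_network_size(self):
        # a 6x12 network with 18 links has fill 0.25
        entries = np.zeros((6, 12), dtype=int)
        entries.flat[np.arange(18)] = 1
        assert density(IncidenceMatrix.from_array(entries)) == 0.25


class TestDropEmpty:
    def test_strips_empty_lines(self):
        m = IncidenceMatrix.from_array([[1, 0], [0, 0]])
        cleaned, dropped_rows, dropped_cols = drop_empty(m)
        assert cleaned.entries.tolist() == [[1]]
        assert dropped_rows == ("R2",) and dropped_cols == ("C2",)

    def test_identity_when_no_empty_lines(self, tiny_matrix):
        cleaned, dropped_rows, dropped_cols = drop_empty(tiny_matrix)
        assert cleaned is tiny_matrix
        assert dropped_rows == () and dropped_cols == ()

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty network"):
            drop_empty(IncidenceMatrix.from_array(np.zeros((2, 2))))


class TestReorder:
    def test_identity_ranking_is_identity(self, tiny_matrix):
        out = reorder(tiny_matrix, Ranking.identity(2, 2))
        assert (out.entries == tiny_matrix.entries).all()
        assert out.row_labels == tiny_matrix.row_labels

    def test_row_swap(self, checker_matrix):
        r = Ranking(np.array([2, 1]), np.array([1, 2]))
        assert reorder(checker_matrix, r).entries.tolist() == [[0, 1], [1, 0]]

    def test_dimension_mismatch_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="do not match"):
            reorder(tiny_matrix, Ranking.identity(3, 2))

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_preserves_links_fill_and_degree_multisets(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        n, m = data.draw(st.integers(2, 6)), data.draw(st.integers(2, 6))
        mat = random_incidence(rng, n, m)
        r = Ranking(rng.permutation(n) + 1, rng.permutation(m) + 1)
        out = reorder(mat, r)
        assert out.n_links == mat.n_links and out.fill == mat.fill
        assert sorted(out.row_degrees) == sorted(mat.row_degrees)
        assert sorted(out.col_degrees) == sorted(mat.col_degrees)

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_reorder_then_inverse_recovers_matrix(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        n, m = data.draw(st.integers(2, 6)), data.draw(st.integers(2, 6))
        mat = random_incidence(rng, n, m)
        fwd = Ranking(rng.permutation(n) + 1, rng.permutation(m) + 1)
        restored = reorder(reorder(mat, fwd), _inverse(fwd))
        assert (restored.entries == mat.entries).all()
        assert restored.row_labels == mat.row_labels
        assert restored.col_labels == mat.col_labels


def _inverse(r: Ranking) -> Ranking:
    """Ranking that undoes reordering by *r*.

    The row placed at position ``pos`` by *r* came from input index
    ``perm[pos]``; giving it rank ``perm[pos] + 1`` sends it back.
    """
    return Ranking(r.row_permutation + 1, r.col_permutation + 1)


class TestDegreeRanking:
    def test_ranks_by_decreasing_degree(self):
        m = IncidenceMatrix.from_array([[1, 0, 0], [1, 1, 1], [1, 1, 0]])
        r = degree_ranking(m)
        assert r.row_order.tolist() == [3, 1, 2]

    def test_ties_keep_input_order(self):
        m = IncidenceMatrix.from_array([[1, 0], [0, 1]])
        r = degree_ranking(m)
        assert r.row_order.tolist() == [1, 2]
        assert r.col_order.tolist() == [1, 2]

    def test_staircase_orientation_recovered_from_shuffle(self, rng):
        stair = np.tril(np.ones((5, 5), dtype=int))
        m = IncidenceMatrix.from_array(stair)
        shuffled = reorder(m, Ranking(rng.permutation(5) + 1, rng.permutation(5) + 1))
        packed = reorder(shuffled, degree_ranking(shuffled))
        # nested neighborhoods: each row's links are a subset of the rows above
        e = packed.entries.astype(bool)
        for i in range(1, 5):
            assert not (e[i] & ~e[i - 1]).any()


class TestIO:
    def test_binarization_threshold(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text(",c1,c2\nr1,3,0\nr2,0,1\n")
        m = read_incidence(f)
        assert m.entries.tolist() == [[1, 0], [0, 1]]
        assert m.row_labels == ("r1", "r2") and m.col_labels == ("c1", "c2")

    def test_empty_file_errors(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_incidence(f)

    def test_non_numeric_cell_errors(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text(",c1\nr1,abc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_incidence(f)

    def test_ragged_rows_error(self, tmp_path):
        f = tmp_path / "ragged.csv"
        f.write_text(",c1,c2\nr1,1\nr2,1,0\n")
        with pytest.raises(ValueError, match="ragged|missing"):
            read_incidence(f)

    def test_edge_list(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("a\tx\na\ty\nb\tx\nc\ty\n")
        m = read_incidence(f, dialect="edge-list")
        assert (m.n_rows, m.n_cols, m.n_links) == (3, 2, 4)

    def test_transpose_flag(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text(",c1,c2\nr1,1,1\nr2,0,1\n")
        m = read_incidence(f, transpose=True)
        assert m.row_labels == ("c1", "c2")
        assert m.entries.tolist() == [[1, 0], [1, 1]]

    def test_round_trip(self, tmp_path, rng):
        m = random_incidence(rng, 5, 7)
        path = tmp_path / "rt.csv"
        write_incidence(m, path)
        back = read_incidence(path)
        assert (back.entries == m.entries).all()
        assert back.row_labels == m.row_labels and back.col_labels == m.col_labels
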