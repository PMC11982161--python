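import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechcoord import (
    ConfigurationError,
    LineStatistics,
    build_crp,
    dyad_measures,
    extract_lines,
    lam_ard,
    line_statistics,
    tt_ard,
)

from .conftest import make_dyad, random_dyad
from .oracle import naive_line_stats, naive_lines, naive_matrix

GRID = np.array([[1, 0, 0], [1, 0, 1], [1, 0, 0]], dtype=bool)


class TestExtractLines:
    def test_vertical_run(self):
        assert extract_lines(GRID, "vertical") == [3]

    def test_no_horizontal_pairs(self):
        assert extract_lines(GRID, "horizontal") == []

    def test_full_small_grid(self):
        ones = np.ones((2, 2), dtype=bool)
        assert extract_lines(ones, "vertical") == [2, 2]
        assert extract_lines(ones, "horizontal") == [2, 2]

    def test_min_length_config(self):
        with pytest.raises(ConfigurationError):
            extract_lines(GRID, "vertical", l_min=1)


class TestLineStatistics:
    def test_sustained_block(self):
        # A speaks twice then silent, B silent throughout: two full vertical
        # columns of 3 and three horizontal runs of 2.
        stats = line_statistics(build_crp(make_dyad([1, 1, 0], [0, 0, 0])))
        assert stats.lam_ver == 1.0
        assert stats.lam_hor == 1.0
        assert stats.tt_ver == 3.0
        assert stats.tt_hor == 2.0

    def test_empty_plot_all_zero(self):
        stats = line_statistics(build_crp(make_dyad([0, 1, 0], [0, 1, 0])))
        assert stats == LineStatistics(0, 0, 0, 0, 2, 0, 0)

    def test_raw_grid(self):
        stats = line_statistics(GRID)
        assert stats.lam_ver == pytest.approx(0.75)  # 3 of 4 points on the run
        assert stats.lam_hor == 0.0
        assert stats.tt_ver == 3.0
        assert stats.tt_hor == 0.0


class TestArds:
    def test_fully_one_sided(self):
        assert lam_ard(LineStatistics(0.75, 0.0, 3, 0, 2, 1, 0)) == 1.0

    def test_balanced(self):
        assert lam_ard(LineStatistics(0.9, 0.9, 3, 3, 2, 1, 1)) == 0.0
        assert tt_ard(LineStatistics(0.9, 0.9, 3, 3, 2, 1, 1)) == 0.0

    def test_degenerate_zero(self):
        assert lam_ard(LineStatistics(0, 0, 0, 0, 2, 0, 0)) == 0.0
        assert tt_ard(LineStatistics(0, 0, 0, 0, 2, 0, 0)) == 0.0

    def test_tt_ratio(self):
        assert tt_ard(LineStatistics(1, 1, 3, 2, 2, 1, 1)) == pytest.approx(0.2)


class TestDyadMeasures:
    def test_constant_identical_series_cascade_to_zero(self):
        # An empty plot (possible only when both partners hold the same
        # constant state) sends every measure to its 0 convention.
        vals = np.zeros(60, dtype=int)
        m = dyad_measures(make_dyad(vals, vals), max_lag=5)
        assert (m.rr_global, m.rr_los, m.q_dcrp, m.lam_ard, m.tt_ard) == (0, 0, 0, 0, 0)

    def test_identical_nonconstant_series_have_empty_los(self):
        vals = np.resize([1, 1, 0], 60)
        m = dyad_measures(make_dyad(vals, vals), max_lag=5)
        assert m.rr_los == 0.0
        assert m.rr_global > 0  # off-diagonal XOR matches remain

    def test_antiphase_construction(self):
        a = np.resize([1, 0], 300)
        m = dyad_measures(make_dyad(a, 1 - a), max_lag=30)
        assert m.rr_los == 1.0

    def test_partner_swap(self):
        rng = np.random.default_rng(3)
        d = random_dyad(rng, n=40)
        swapped = make_dyad(d.series_b.values, d.series_a.values)
        m1 = dyad_measures(d, max_lag=5)
        m2 = dyad_measures(swapped, max_lag=5)
        assert m1.rr_global == m2.rr_global
        assert m1.rr_los == m2.rr_los
        assert m1.q_dcrp == pytest.approx(m2.q_dcrp)
        assert m1.lam_ard == pytest.approx(m2.lam_ard)
        assert m1.tt_ard == pytest.approx(m2.tt_ard)
        assert m1.line_stats.lam_ver == m2.line_stats.lam_hor
        assert m1.line_stats.tt_ver == m2.line_stats.tt_hor


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_transpose_duality_random_grids(data):
    """Transposing the grid swaps vertical and horizontal statistics."""
    n = data.draw(st.integers(2, 12))
    m = data.draw(st.integers(2, 12))
    flat = data.draw(st.lists(st.booleans(), min_size=n * m, max_size=n * m))
    grid = np.array(flat).reshape(n, m)
    s, st_t = line_statistics(grid), line_statistics(grid.T)
    assert s.lam_ver == pytest.approx(st_t.lam_hor)
    assert s.tt_ver == st_t.tt_hor
    assert lam_ard(s) == pytest.approx(lam_ard(st_t))
    assert tt_ard(s) == pytest.approx(tt_ard(st_t))


def test_line_extraction_matches_naive_cell_walk():
    rng = np.random.default_rng(9)
    for _ in range(30):
        d = random_dyad(rng, p=rng.uniform(0.2, 0.8), q=rng.uniform(0.2, 0.8))
        a, b = d.series_a.values.tolist(), d.series_b.values.tolist()
        mat = naive_matrix(a, b)
        crp = build_crp(d)
        for direction in ("vertical", "horizontal"):
            assert extract_lines(crp.matrix, direction) == naive_lines(mat, direction, 2)
        stats = line_statistics(crp)
        ref = naive_line_stats(a, b, 2)
        assert stats.lam_ver == pytest.approx(ref["lam_ver"])
        assert stats.lam_hor == pytest.approx(ref["lam_hor"])
        assert stats.tt_ver == pytest.approx(ref["tt_ver"])
        assert stats.tt_hor == pytest.approx(ref["tt_hor"])


def test_vertical_runs_are_runs_of_complementary_b():
    """In column i, vertical runs are exactly maximal runs of b == 1 - a_i."""
    from .oracle import _naive_runs

    rng = np.random.default_rng(21)
    for _ in range(20):
        d = random_dyad(rng)
        b = d.series_b.values
        mat = build_crp(d).matrix
        for i, ai in enumerate(d.series_a.values):
            assert _naive_runs(mat[:, i].astype(int).tolist()) == _naive_runs(
                (b == 1 - ai).astype(int).tolist()
            )


def test_tt_in_valid_range():
    rng = np.random.default_rng(17)
    for _ in range(20):
        d = random_dyad(rng)
        stats = line_statistics(build_crp(d), l_min=2)
        for tt in (stats.tt_ver, stats.tt_hor):
            assert tt == 0 or 2 <= tt <= d.n
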