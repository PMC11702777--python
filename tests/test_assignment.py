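import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

from ctsvg.assignment import (
    aggregate_counts,
    approximate_overlap,
    assign_cells,
    assign_squares,
    expand_nucleus,
    filter_large_nuclei,
    remove_abnormal_cells,
)
from ctsvg.containers import STAGE_NUCLEUS, UNASSIGNED, NucleusPolygon, SquareAssignment
from ctsvg.synthetic import TissueSpec, generate_tissue, _ellipse

from conftest import make_counts, make_grid, square_nucleus


class TestFilterLargeNuclei:
    def test_zero_variance_retains_all(self):
        nuclei = [square_nucleus(i, (10 * i, 0), np.e) for i in range(10)]
        assert len(filter_large_nuclei(nuclei)) == 10

    def test_outlier_removed_by_log_area_cutoff(self):
        # log areas {1 x9, 20}: mean 2.9, sd 6.0083, cutoff 14.9166
        nuclei = [square_nucleus(i, (100 * i, 0), np.e) for i in range(9)]
        nuclei.append(square_nucleus(9, (0, 1e6), np.exp(20)))
        kept = filter_large_nuclei(nuclei)
        assert [n.nucleus_id for n in kept] == list(range(9))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_large_nuclei([])

    def test_single_nucleus_retained_with_warning(self, caplog):
        nuclei = [square_nucleus(0, (0, 0), 5.0)]
        assert filter_large_nuclei(nuclei) == nuclei


class TestApproximateOverlap:
    def test_square_inside_nucleus(self):
        poly = box(-10, -10, 10, 10)
        assert approximate_overlap((1.0, 1.0), 2.0, poly) == pytest.approx(4.0)

    def test_square_outside(self):
        poly = box(10, 10, 12, 12)
        assert approximate_overlap((1.0, 1.0), 2.0, poly) == 0.0

    def test_half_plane_covers_fifty_subsquares(self):
        # left half of the [0,2)^2 square: centroids at x = 0.1..0.9 inside
        poly = box(-100, -100, 1.0, 100)
        approx = approximate_overlap((1.0, 1.0), 2.0, poly)
        exact = box(0, 0, 2, 2).intersection(poly).area
        assert approx == pytest.approx(2.0)
        assert approx == pytest.approx(exact)

    def test_error_bound_on_random_ellipses(self, rng):
        sub_w = 2.0 / 10
        for _ in range(200):
            center = rng.uniform(-2, 2, 2)
            poly = _ellipse(center, rng.uniform(4, 20), rng.uniform(0.6, 1.0), rng.uniform(0, np.pi), 64)
            approx = approximate_overlap((0.0, 0.0), 2.0, poly)
            exact = box(-1, -1, 1, 1).intersection(poly).area
            assert abs(approx - exact) <= 4 * poly.exterior.length * sub_w


class TestAssignSquares:
    def test_single_nucleus_claims_square(self):
        grid = make_grid(1, 1)
        nuc = square_nucleus(3, (1.0, 1.0), 1.0)
        a = assign_squares(grid, [nuc])
        assert a.cell.tolist() == [3]
        assert a.stage.tolist() == [STAGE_NUCLEUS]

    def test_argmax_sixty_vs_forty(self):
        grid = make_grid(1, 1)  # square [0,2)x[0,2)
        left = NucleusPolygon(1, box(-100, -100, 1.2, 100))   # 60 centroids
        right = NucleusPolygon(2, box(1.2, -100, 100, 100))   # 40 centroids
        a = assign_squares(grid, [left, right])
        assert a.cell.tolist() == [1]
        a2 = assign_squares(make_grid(1, 1), [NucleusPolygon(1, box(1.2, -100, 100, 100)), NucleusPolygon(2, box(-100, -100, 1.2, 100))])
        assert a2.cell.tolist() == [2]

    def test_tie_breaks_to_smaller_id(self):
        grid = make_grid(1, 1)
        left = NucleusPolygon(5, box(-100, -100, 1.0, 100))
        right = NucleusPolygon(2, box(1.0, -100, 100, 100))
        a = assign_squares(grid, [left, right])
        assert a.cell.tolist() == [2]

    def test_second_pass_never_reassigns(self):
        grid = make_grid(1, 2)
        first = square_nucleus(0, (1.0, 1.0), 16.0)  # covers both squares
        a = assign_squares(grid, [first])
        assert a.cell.tolist() == [0, 0]
        big = square_nucleus(1, (2.0, 1.0), 400.0)
        a2 = assign_squares(grid, [big], existing=a, stage=2)
        assert a2.cell.tolist() == [0, 0]


class TestExpandNucleus:
    def test_ratio_one_is_identity(self):
        nuc = square_nucleus(0, (3.0, 4.0), 7.0)
        out = expand_nucleus(nuc, 1.0)
        np.testing.assert_allclose(out.contour, nuc.contour, atol=1e-12)

    def test_unit_square_doubles_area(self):
        nuc = square_nucleus(0, (0.0, 0.0), 1.0)
        out = expand_nucleus(nuc, 2.0)
        assert out.area == pytest.approx(2.0, abs=1e-12)
        side = out.contour[:, 0].max() - out.contour[:, 0].min()
        assert side == pytest.approx(np.sqrt(2.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(1.0, 10.0), st.integers(0, 1000))
    def test_area_ratio_exact_and_similarity(self, ratio, seed):
        rng = np.random.default_rng(seed)
        poly = _ellipse(rng.uniform(-50, 50, 2), rng.uniform(2, 80), rng.uniform(0.5, 1.0), rng.uniform(0, np.pi))
        nuc = NucleusPolygon(0, poly)
        out = expand_nucleus(nuc, ratio)
        assert out.area / nuc.area == pytest.approx(ratio, rel=1e-9)
        # pairwise contour distances scale by exactly sqrt(ratio)
        d0 = np.linalg.norm(nuc.contour[0] - nuc.contour[5])
        d1 = np.linalg.norm(out.contour[0] - out.contour[5])
        assert d1 / d0 == pytest.approx(np.sqrt(ratio), rel=1e-9)

    def test_literal_ratio_compatibility_flag(self):
        nuc = square_nucleus(0, (0.0, 0.0), 1.0)
        out = expand_nucleus(nuc, 2.0, literal_ratio_scaling=True)
        assert out.area == pytest.approx(4.0)

    def test_ratio_below_one_errors(self):
        with pytest.raises(ValueError):
            expand_nucleus(square_nucleus(0, (0, 0), 1.0), 0.5)


class TestRemoveAbnormalCells:
    def _setup(self, n_assigned, nucleus_area=20.0):
        grid = make_grid(1, 8)
        nuc = square_nucleus(1, (8.0, 1.0), nucleus_area)
        exp = expand_nucleus(nuc, 2.0)
        a = SquareAssignment.empty(grid.squares.index)
        a.cell[:n_assigned] = 1
        return a, grid, [nuc], [exp]

    def test_zero_squares_removed(self):
        a, grid, nuclei, exp = self._setup(0)
        assert remove_abnormal_cells(a, grid, nuclei, exp) == []

    def test_area_rule_boundary(self):
        # expanded area 40 um^2; 4 squares (16) removed, 6 squares (24) kept
        a, grid, nuclei, exp = self._setup(4)
        assert remove_abnormal_cells(a, grid, nuclei, exp) == []
        a, grid, nuclei, exp = self._setup(6)
        assert remove_abnormal_cells(a, grid, nuclei, exp) == [1]

    def test_connectivity_rule(self):
        grid = make_grid(1, 3)
        nuc = square_nucleus(1, (3.0, 1.0), 1.0)
        exp = expand_nucleus(nuc, 2.0)
        a = SquareAssignment.empty(grid.squares.index)
        a.cell[[0, 2]] = 1  # gap at col 1
        assert remove_abnormal_cells(a, grid, [nuc], [exp]) == []
        a.cell[:] = UNASSIGNED
        a.cell[[0, 1]] = 1
        assert remove_abnormal_cells(a, grid, [nuc], [exp]) == [1]


class TestAggregate:
    def test_two_square_sum(self):
        grid = make_grid(1, 2)
        counts = make_counts(grid, [[1, 2]])
        nuc = square_nucleus(1, (2.0, 1.0), 4.0)
        a = SquareAssignment.empty(grid.squares.index)
        a.cell[:] = 1
        cells = aggregate_counts(a, counts, [1], [nuc], [expand_nucleus(nuc, 2.0)])
        assert cells.counts.toarray().tolist() == [[3]]
        assert cells.cells.iloc[0][["x", "y"]].tolist() == [2.0, 1.0]

    def test_all_unassigned_gives_empty_matrix(self):
        grid = make_grid(1, 2)
        counts = make_counts(grid, [[1, 2]])
        a = SquareAssignment.empty(grid.squares.index)
        cells = aggregate_counts(a, counts, [], [], [])
        assert cells.n_cells == 0

    def test_generator_ground_truth_totals(self):
        from ctsvg.synthetic import generate_ideal_tissue

        tissue = generate_ideal_tissue(n_side=3, seed=4)
        cells, _ = assign_cells(tissue.grid, tissue.square_counts, tissue.nuclei)
        totals = np.asarray(cells.counts.sum(axis=0)).ravel()
        truth = tissue.transcripts.table.groupby("gold_cell").size()
        for cid, total in zip(cells.cells.index, totals):
            assert total == truth.get(int(cid), 0)


class TestPipelineInvariants:
    def test_count_conservation(self):
        tissue = generate_tissue(TissueSpec(n_cells=25, n_genes=12, arena=(160.0, 160.0), seed=9))
        cells, assignment = assign_cells(tissue.grid, tissue.square_counts, tissue.nuclei)
        total_in = tissue.square_counts.counts.sum()
        retained = set(int(c) for c in cells.cells.index)
        unassigned_or_dropped = ~np.isin(assignment.cell, list(retained))
        leftover = tissue.square_counts.counts[:, unassigned_or_dropped].sum()
        assert cells.counts.sum() + leftover == total_in

    def test_argmax_agrees_with_exact_clipping(self, rng):
        # approximate argmax matches exact polygon clipping on >= 95% of configs
        agree = trials = 0
        for _ in range(200):
            polys = [
                NucleusPolygon(i, _ellipse(rng.uniform(-2.5, 2.5, 2), rng.uniform(4, 25), rng.uniform(0.6, 1.0), rng.uniform(0, np.pi), 48))
                for i in range(2)
            ]
            approx = [approximate_overlap((0.0, 0.0), 2.0, p.polygon) for p in polys]
            exact = [box(-1, -1, 1, 1).intersection(p.polygon).area for p in polys]
            trials += 1
            a = -1 if max(approx) == 0 else int(np.argmax(approx))
            e = -1 if max(exact) == 0 else int(np.argmax(exact))
            agree += a == e
        assert agree / trials >= 0.95
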