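import numpy as np
import pandas as pd
import pytest

from ctsvg.containers import UNASSIGNED, CellMatrix, NucleusPolygon, TranscriptTable
from ctsvg.evaluation import (
    bin8_baseline,
    bin_transcripts,
    clustering_agreement,
    drop_controls,
    evaluate_tissue,
    expression_agreement,
    gridify,
    mapping_accuracy,
    resolve_bin8_transcripts,
    subset_rectangle,
    transcript_squares,
)
from ctsvg.synthetic import TissueSpec, generate_ideal_tissue, generate_tissue

from conftest import square_nucleus


def _transcripts(xy, genes=None, gold=None):
    xy = np.asarray(xy, dtype=float)
    return TranscriptTable(
        table=pd.DataFrame(
            {
                "x": xy[:, 0],
                "y": xy[:, 1],
                "gene": genes if genes is not None else ["g0"] * len(xy),
                "gold_cell": gold if gold is not None else UNASSIGNED,
            }
        )
    )


class TestSubsetRectangle:
    def test_frac_one_is_identity(self, rng):
        xy = rng.uniform(0, 100, size=(50, 2))
        nuclei = [square_nucleus(i, c, 4.0) for i, c in enumerate(rng.uniform(10, 90, (5, 2)))]
        tr, nuc, cells = subset_rectangle(_transcripts(xy), nuclei, nuclei, frac=1.0)
        assert len(tr) == 50 and len(nuc) == 5

    def test_uniform_retention_matches_area_fraction(self, rng):
        n = 4000
        xy = rng.uniform(0, 100, size=(n, 2))
        nuclei = [square_nucleus(0, (50, 50), 4.0)]
        tr, _, _ = subset_rectangle(_transcripts(xy), nuclei, nuclei, frac=0.5)
        expected = 0.25 * n
        sd = np.sqrt(n * 0.25 * 0.75)
        assert abs(len(tr) - expected) < 3 * sd

    def test_zero_frac_errors(self, rng):
        xy = rng.uniform(0, 10, size=(10, 2))
        with pytest.raises(ValueError):
            subset_rectangle(_transcripts(xy), [], [], frac=0.0)


class TestDropControls:
    def test_prefixes_removed_others_kept(self):
        genes = [
            "NegControlProbe_00042",
            "NegControlCodeword_1",
            "UnassignedCodeword_9",
            "ACTB",
            "Lhx8",
        ]
        tr = _transcripts(np.zeros((5, 2)), genes=genes)
        out = drop_controls(tr)
        assert list(out.table["gene"]) == ["ACTB", "Lhx8"]

    def test_mixed_fixture_count(self):
        genes = ["NegControlProbe_1"] * 3 + ["g"] * 7
        out = drop_controls(_transcripts(np.zeros((10, 2)), genes=genes))
        assert len(out) == 7


class TestGridify:
    def test_ten_by_ten_box(self):
        grid = gridify((0, 0, 10, 10), 2.0)
        assert grid.n_squares == 25

    def test_box_smaller_than_square(self):
        assert gridify((0, 0, 1, 1), 2.0).n_squares == 1

    def test_every_transcript_in_exactly_one_square(self, rng):
        xy = rng.uniform(0, 10, size=(300, 2))
        tr = _transcripts(xy)
        _, counts = bin_transcripts(tr, (0, 0, 10, 10), 2.0)
        assert counts.counts.sum() == 300


class TestBin8:
    def test_cell_inside_one_square(self):
        grid8 = gridify((0, 0, 16, 16), 8.0)
        cell = square_nucleus(1, (4.0, 4.0), 9.0)
        out = bin8_baseline([cell], grid8)
        assert grid8.squares.iloc[out[1]][["row", "col"]].tolist() == [0, 0]

    def test_seventy_thirty_straddle(self):
        grid8 = gridify((0, 0, 16, 8), 8.0)
        # rectangle covering 70% of square 0 and 30% of square 1
        from shapely.geometry import box

        cell = NucleusPolygon(1, box(2.4, 1.0, 10.4, 7.0))
        out = bin8_baseline([cell], grid8)
        assert grid8.squares.iloc[out[1]]["col"] == 0

    def test_shared_square_double_counts_expression(self):
        from ctsvg.evaluation import bin8_cell_counts

        grid8 = gridify((0, 0, 8, 8), 8.0)
        cells = [square_nucleus(1, (3.0, 3.0), 4.0), square_nucleus(2, (5.0, 5.0), 4.0)]
        c2s = bin8_baseline(cells, grid8)
        assert c2s[1] == c2s[2]
        tr = _transcripts([[1.0, 1.0], [6.0, 6.0]], genes=["g0", "g0"])
        sq = transcript_squares(tr, (0, 0, 8, 8), 8.0)
        cm = bin8_cell_counts(tr, c2s, sq)
        assert cm.counts.toarray().tolist() == [[2, 2]]

    def test_tie_resolution_is_seeded(self):
        grid8 = gridify((0, 0, 8, 8), 8.0)
        cells = [square_nucleus(1, (3.0, 3.0), 4.0), square_nucleus(2, (5.0, 5.0), 4.0)]
        c2s = bin8_baseline(cells, grid8)
        tr = _transcripts(np.full((6, 2), 4.0))
        sq = transcript_squares(tr, (0, 0, 8, 8), 8.0)
        a = resolve_bin8_transcripts(sq, c2s, rng_seed=0)
        b = resolve_bin8_transcripts(sq, c2s, rng_seed=0)
        np.testing.assert_array_equal(a, b)
        assert set(a) <= {1, 2}


class TestMappingAccuracy:
    def test_perfect(self):
        assert mapping_accuracy([1, 2, UNASSIGNED], [1, 2, UNASSIGNED]) == 1.0

    def test_half_flipped(self):
        gold = np.array([1, 1, 2, 2])
        pred = np.array([1, 1, 9, 9])
        assert mapping_accuracy(pred, gold) == 0.5

    def test_all_unassigned_vs_assigned(self):
        assert mapping_accuracy([UNASSIGNED] * 4, [1, 2, 3, 4]) == 0.0


def _counts_matrix(dense, ids):
    import scipy.sparse as sp

    dense = np.asarray(dense)
    return CellMatrix(
        genes=pd.Index([f"g{i}" for i in range(dense.shape[0])]),
        cells=pd.DataFrame(
            {"x": np.zeros(dense.shape[1]), "y": np.zeros(dense.shape[1])},
            index=pd.Index(ids),
        ),
        counts=sp.csr_matrix(dense),
    )


class TestExpressionAgreement:
    def test_identical_matrices(self, rng):
        dense = rng.poisson(5.0, size=(30, 8)) + 1
        ids = [f"c{i}" for i in range(8)]
        a = _counts_matrix(dense, ids)
        assert expression_agreement(a, _counts_matrix(dense, ids)) == pytest.approx(1.0)

    def test_small_noise_keeps_high_correlation(self, rng):
        dense = rng.poisson(20.0, size=(40, 10)) + 1
        ids = [f"c{i}" for i in range(10)]
        noisy = dense.copy()
        noisy[rng.uniform(size=dense.shape) < 0.05] += 1
        med = expression_agreement(_counts_matrix(noisy, ids), _counts_matrix(dense, ids))
        assert med > 0.99

    def test_too_few_shared_cells_errors(self, rng):
        dense = rng.poisson(5.0, size=(10, 2)) + 1
        a = _counts_matrix(dense, ["c0", "c1"])
        with pytest.raises(ValueError):
            expression_agreement(a, a)


class TestClusteringAgreement:
    def test_identical_labelings(self):
        assert clustering_agreement([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_singletons_vs_one_cluster(self):
        assert clustering_agreement(range(6), [0] * 6) == 0.0

    def test_random_permutation_near_zero(self, rng):
        labels = np.repeat(np.arange(4), 25)
        aris = [
            clustering_agreement(labels, rng.permutation(labels)) for _ in range(200)
        ]
        assert abs(np.mean(aris)) < 0.02


class TestEvaluateTissue:
    def test_ideal_tissue_perfect_for_ctsvg_only(self):
        tissue = generate_ideal_tissue(n_side=4, seed=2)
        arena = tissue.spec.arena
        report = evaluate_tissue(
            tissue.transcripts,
            tissue.nuclei,
            tissue.cells,
            rng_seed=0,
            bounds=(0.0, 0.0, arena[0], arena[1]),
        )
        assert report.loc["ctsvg", "accuracy"] == 1.0
        assert report.loc["bin8", "accuracy"] < 1.0

    def test_ctsvg_dominates_on_random_tissue(self):
        tissue = generate_tissue(TissueSpec(seed=11))
        arena = tissue.spec.arena
        report = evaluate_tissue(
            tissue.transcripts,
            tissue.nuclei,
            tissue.cells,
            rng_seed=0,
            bounds=(0.0, 0.0, arena[0], arena[1]),
        )
        for metric in ("accuracy", "correlation", "ari"):
            assert report.loc["ctsvg", metric] >= report.loc["bin8", metric]
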