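"""The model/results facade, the end-to-end pipeline runner and the CLI."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from typer.testing import CliRunner

from ctsvg import io
from ctsvg.benchmarks import _recovery_dataset
from ctsvg.cli import app
from ctsvg.model import SpatialSVG
from ctsvg.pipeline import RunConfig, run_pipeline
from ctsvg.preprocessing import GraphClustering
from ctsvg.synthetic import TissueSpec, generate_tissue


@pytest.fixture(scope="module")
def fitted_results():
    cells, expr, flags = _recovery_dataset(600, 15, 60, effect=1.2, noise_sd=0.3, seed=8)
    clustering = GraphClustering(sp.csr_matrix(expr), n_pcs=10, resolution=0.1)
    model = SpatialSVG(cells, labels=clustering.cluster(0), n_knots=2, normalized=expr)
    results = model.fit().test(clustering, n_seeds=30, keep=30, rng_seed=8)
    return results, flags


class TestModelFacade:
    def test_summary_schema_and_ranking(self, fitted_results):
        results, _ = fitted_results
        df = results.summary()
        assert {"cluster", "gene", "F", "p", "fdr", "rank", "significant"} <= set(df.columns)
        for _, sub in df.groupby("cluster"):
            assert sub["rank"].tolist() == sorted(sub["rank"].tolist())
            assert (sub["fdr"] >= sub["p"] - 1e-12).all()
            assert sub["p"].between(0, 1).all()

    def test_planted_genes_lead_the_ranking(self, fitted_results):
        results, flags = fitted_results
        for c in results.tables:
            top = results.summary(cluster=c).head(15)["gene"]
            assert (flags.loc[top] == 1).mean() > 0.8

    def test_rerun_is_deterministic(self, fitted_results):
        results, _ = fitted_results
        cells = results.model.cells
        expr = results.model.normalized
        clustering = GraphClustering(sp.csr_matrix(expr), n_pcs=10, resolution=0.1)
        again = (
            SpatialSVG(cells, labels=clustering.cluster(0), n_knots=2, normalized=expr)
            .fit()
            .test(clustering, n_seeds=30, keep=30, rng_seed=8)
        )
        for c in results.tables:
            pd.testing.assert_frame_equal(results.tables[c], again.tables[c])

    def test_standardized_fits_are_standardized(self, fitted_results):
        results, _ = fitted_results
        c = next(iter(results.cluster_fits))
        std = results.standardized_fits(c)
        np.testing.assert_allclose(std.mean(axis=1), 0.0, atol=1e-9)
        sds = std.to_numpy().std(axis=1, ddof=1)
        np.testing.assert_allclose(sds[sds > 0], 1.0, rtol=1e-9)

    def test_parametric_baseline_monotone_in_f(self, fitted_results):
        results, _ = fitted_results
        c = next(iter(results.cluster_fits))
        base = results.parametric_baseline(c).sort_values("F")
        assert (np.diff(base["p"].to_numpy()) <= 1e-12).all()

    def test_missing_labels_error(self, fitted_results):
        results, _ = fitted_results
        cells = results.model.cells
        cells.labels = None
        with pytest.raises(ValueError, match="labels"):
            SpatialSVG(cells)


@pytest.fixture(scope="module")
def tissue_tree(tmp_path_factory):
    out = tmp_path_factory.mktemp("tissue")
    tissue = generate_tissue(TissueSpec(n_cells=200, n_genes=40, arena=(500.0, 500.0), seed=21))
    io.write_nuclei_geojson(tissue.nuclei, out / "nuclei.geojson")
    io.write_visiumhd(tissue.grid, tissue.square_counts, out / "visiumhd")
    return out


def _config(tissue_tree, outdir) -> RunConfig:
    return RunConfig(
        matrix=str(tissue_tree / "visiumhd" / "matrix"),
        positions=str(tissue_tree / "visiumhd" / "tissue_positions.csv"),
        scalefactors=str(tissue_tree / "visiumhd" / "scalefactors_json.json"),
        nuclei=str(tissue_tree / "nuclei.geojson"),
        out=str(outdir),
        min_genes=5,
        min_cell_frac=0.0,
        resolution=0.5,
        knots=0,
        n_seeds=20,
        keep=10,
        rng_seed=0,
    )


class TestPipeline:
    def test_full_run_produces_stage_artifacts(self, tissue_tree, tmp_path):
        out = run_pipeline(_config(tissue_tree, tmp_path / "run1"))
        assert (out / "config.json").exists()
        assert (out / "cells" / "cells.tsv").exists()
        assert (out / "square_assignment.tsv").exists()
        assert (out / "clusters.tsv").exists()
        assert (out / "svg").is_dir()

    def test_rerun_identical_svg_tables(self, tissue_tree, tmp_path):
        out1 = run_pipeline(_config(tissue_tree, tmp_path / "a"))
        out2 = run_pipeline(_config(tissue_tree, tmp_path / "b"))
        files1 = sorted((out1 / "svg").glob("*.tsv"))
        files2 = sorted((out2 / "svg").glob("*.tsv"))
        assert [f.name for f in files1] == [f.name for f in files2]
        for f1, f2 in zip(files1, files2):
            assert f1.read_bytes() == f2.read_bytes()

    def test_missing_nuclei_fails_before_compute(self, tmp_path):
        config = RunConfig(matrix="m", positions="p", scalefactors="s", out=str(tmp_path))
        with pytest.raises(ValueError, match="nuclei"):
            run_pipeline(config)


class TestCLI:
    def test_simulate_assign_cluster_chain(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(app, ["simulate", "--out", str(sim), "--seed", "5", "--n-cells", "60"])
        assert r.exit_code == 0, r.output
        assert (sim / "nuclei.geojson").exists()

        cells_dir = tmp_path / "cells"
        r = runner.invoke(
            app,
            [
                "assign",
                "--matrix", str(sim / "visiumhd" / "matrix"),
                "--positions", str(sim / "visiumhd" / "tissue_positions.csv"),
                "--scalefactors", str(sim / "visiumhd" / "scalefactors_json.json"),
                "--nuclei", str(sim / "nuclei.geojson"),
                "--out", str(cells_dir),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (cells_dir / "cells.tsv").exists()

        clusters = tmp_path / "clusters.tsv"
        r = runner.invoke(
            app,
            [
                "cluster",
                "--cells", str(cells_dir),
                "--out", str(clusters),
                "--min-genes", "5",
                "--min-cell-frac", "0",
                "--resolution", "0.5",
            ],
        )
        assert r.exit_code == 0, r.output
        labels = pd.read_csv(clusters, sep="\t")
        assert {"cell", "cluster"} <= set(labels.columns)

    def test_eval_command(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(app, ["simulate", "--out", str(sim), "--seed", "2", "--ideal"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            app,
            [
                "eval",
                "--transcripts", str(sim / "transcripts.csv"),
                "--nuclei", str(sim / "nuclei.geojson"),
                "--cells-gold", str(sim / "cells_gold.geojson"),
                "--out", str(tmp_path / "report.json"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "report.json").exists()
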