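"""End-to-end pipeline runner with a serializable configuration.

``RunConfig`` captures every stage parameter and path; ``run_pipeline``
executes assign -> cluster -> fit/test -> modules, writing each stage's
artifacts under the output directory together with the config and a log of
parameters and seeds.  Stages whose outputs already exist are skipped, so
partial runs resume; identical config + seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import CellMatrix
from .downstream import cluster_gene_modules, enrich_gene_sets, metagene
from .model import SpatialSVG
from .preprocessing import GraphClustering, lognormalize, qc_filter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # inputs
    matrix: str | None = None
    positions: str | None = None
    scalefactors: str | None = None
    nuclei: str | None = None
    counts: str | None = None       # generic mode
    coords: str | None = None       # generic mode
    out: str = "ctsvg_out"
    gmt: str | None = None
    # stage parameters
    area_ratio: float = 2.0
    min_genes: int = 300
    min_cell_frac: float = 0.01
    scale_factor: float = 1e4
    n_pcs: int = 10
    n_hvg: int = 2000
    n_neighbors: int = 20
    resolution: float = 1.2
    cluster_seed: int = 0
    knots: int = 2
    n_seeds: int = 1000
    keep: int = 100
    fdr: float = 0.05
    rng_seed: int = 0
    k_max_modules: int = 15

    def validate(self) -> None:
        visium = all(x is not None for x in (self.matrix, self.positions, self.scalefactors))
        generic = all(x is not None for x in (self.counts, self.coords))
        if visium and self.nuclei is None:
            raise ValueError("Visium HD mode requires a nuclei GeoJSON path")
        if not visium and not generic:
            raise ValueError(
                "either (matrix, positions, scalefactors, nuclei) or (counts, coords) required"
            )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            data = json.load(f)
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)


def _stage_assign(config: RunConfig, outdir: Path) -> CellMatrix:
    cells_dir = outdir / "cells"
    if (cells_dir / "cells.tsv").exists():
        logger.info("assign: reusing %s", cells_dir)
        return io.read_cell_matrix(cells_dir)
    if config.counts is not None:
        cells = io.read_generic(config.counts, config.coords)
    else:
        from .assignment import assign_cells

        grid, counts = io.read_visiumhd(config.matrix, config.positions, config.scalefactors)
        nuclei = io.read_nuclei_geojson(config.nuclei)
        cells, assignment = assign_cells(grid, counts, nuclei, area_ratio=config.area_ratio)
        assignment.to_frame().to_csv(outdir / "square_assignment.tsv", sep="\t")
    io.write_cell_matrix(cells, cells_dir)
    return cells


def _stage_cluster(config: RunConfig, outdir: Path, cells: CellMatrix):
    cells = qc_filter(cells, config.min_genes, config.min_cell_frac)
    norm = lognormalize(cells, config.scale_factor)
    clustering = GraphClustering(
        norm,
        n_pcs=config.n_pcs,
        n_neighbors=config.n_neighbors,
        n_hvg=config.n_hvg,
        resolution=config.resolution,
    )
    labels = clustering.cluster(config.cluster_seed)
    pd.DataFrame({"cell": cells.cells.index, "cluster": labels}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    return cells, norm, clustering, labels


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory."""
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")

    cells = _stage_assign(config, outdir)
    cells, norm, clustering, labels = _stage_cluster(config, outdir, cells)

    model = SpatialSVG(cells, labels=labels, n_knots=config.knots, normalized=norm)
    results = model.fit().test(
        clustering,
        n_seeds=config.n_seeds,
        keep=config.keep,
        rng_seed=config.rng_seed,
        fdr_cutoff=config.fdr,
    )
    svg_dir = outdir / "svg"
    svg_dir.mkdir(exist_ok=True)
    for c in sorted(results.cluster_fits):
        results.summary(cluster=c).to_csv(svg_dir / f"cluster_{c}.tsv", sep="\t", index=False)

    modules_dir = outdir / "modules"
    modules_dir.mkdir(exist_ok=True)
    gene_sets = io.read_gmt(config.gmt) if config.gmt else None
    for c, table in results.tables.items():
        sig = table.loc[table["significant"], "gene"].tolist()
        if len(sig) < 2:
            continue
        std = results.standardized_fits(c, genes=sig)
        mods = cluster_gene_modules(std, k_max=config.k_max_modules, seed=config.rng_seed)
        rows = [
            {"module": m.module_id, "gene": g} for m in mods.modules for g in m.genes
        ]
        pd.DataFrame(rows).to_csv(modules_dir / f"cluster_{c}_modules.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            {f"module_{m.module_id}": metagene(m, std) for m in mods.modules},
            index=std.columns,
        )
        meta.to_csv(modules_dir / f"cluster_{c}_metagenes.tsv", sep="\t", index_label="cell")
        if gene_sets:
            universe = table["gene"].tolist()
            for m in mods.modules:
                enr = enrich_gene_sets(m.genes, universe, gene_sets)
                enr.to_csv(
                    modules_dir / f"cluster_{c}_module_{m.module_id}_enrichment.tsv",
                    sep="\t",
                    index=False,
                )
    logger.info("pipeline complete: %s", outdir)
    return outdir
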