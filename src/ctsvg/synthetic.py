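"""Synthetic tissues, expression fields and null datasets.

The generator emulates the structures the pipeline consumes: non-overlapping
elliptical nuclei with whole cells defined as the nuclei scaled to twice the
area about their centroids, transcripts placed uniformly within whole cells
with per-cell-type Poisson rates optionally modulated by a smooth spatial
field evaluated at the cell centroid, a 2 µm lattice count table binned from
the transcripts, and continuous expression matrices with planted spatially
variable genes for parameter-recovery studies.  Every generator is a pure
function of its spec and seed; pixel units equal microns throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon

from .containers import CellMatrix, CountTable, NucleusPolygon, SquareGrid, TranscriptTable
from .evaluation import gridify, transcript_squares


@dataclass
class SVGSpec:
    """A planted spatially variable gene: which gene, in which cell type
    (-1 = all types), with which spatial field and effect size."""

    gene: int
    cell_type: int = -1
    field: str = "linear"  # linear | radial | none
    effect: float = 2.0


@dataclass
class TissueSpec:
    """Study conditions for a synthetic tissue.

    Defaults describe a small but realistic patch: a 400 x 400 µm arena,
    120 cells of 2 types placed in Gaussian blobs, log-normal nucleus areas
    around 60 µm² (sd 0.3 on the log scale), whole cells at twice the
    nucleus area, a 60-gene panel with 10 markers per type at a 10x rate
    ratio, and Poisson transcript counts.
    """

    arena: tuple[float, float] = (400.0, 400.0)
    n_cells: int = 120
    n_types: int = 2
    blob_sd: float = 80.0
    nucleus_log_area_mean: float = float(np.log(60.0))
    nucleus_log_area_sd: float = 0.3
    area_ratio: float = 2.0
    n_genes: int = 60
    n_markers_per_type: int = 10
    base_rate: float = 0.3
    marker_rate: float = 3.0
    svg_genes: list[SVGSpec] = dc_field(default_factory=list)
    seed: int = 0


@dataclass
class SyntheticTissue:
    spec: TissueSpec
    nuclei: list[NucleusPolygon]
    cells: list[NucleusPolygon]  # whole-cell polygons (expanded nuclei)
    cell_types: np.ndarray       # per cell, aligned with nuclei order
    transcripts: TranscriptTable
    grid: SquareGrid
    square_counts: CountTable
    genes: pd.Index


def _ellipse(center, area, axis_ratio, angle, n_points=16) -> Polygon:
    a = np.sqrt(area / (np.pi * axis_ratio))
    b = axis_ratio * a
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return Polygon(
        np.column_stack([center[0] + ca * x - sa * y, center[1] + sa * x + ca * y])
    )


def _field_value(kind: str, xy: np.ndarray, arena) -> float:
    if kind == "linear":
        return float(xy[0] / arena[0])
    if kind == "radial":
        c = np.array(arena) / 2.0
        sigma = min(arena) / 4.0
        return float(np.exp(-np.sum((xy - c) ** 2) / (2 * sigma**2)))
    if kind == "none":
        return 0.0
    raise ValueError(f"unknown field kind: {kind}")


def _rates(spec: TissueSpec) -> np.ndarray:
    rates = np.full((spec.n_types, spec.n_genes), spec.base_rate)
    for t in range(spec.n_types):
        lo = t * spec.n_markers_per_type
        hi = min(lo + spec.n_markers_per_type, spec.n_genes)
        rates[t, lo:hi] = spec.marker_rate
    return rates


def _place_transcripts(rng, cell_poly: Polygon, n: int) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection sampling."""
    xmin, ymin, xmax, ymax = cell_poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(max(4 * (n - got), 16), 2))
        inside = shapely.contains_xy(cell_poly, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def _bin_tissue(transcripts: TranscriptTable, genes: pd.Index, arena, size_um=2.0):
    bounds = (0.0, 0.0, float(arena[0]), float(arena[1]))
    grid = gridify(bounds, size_um)
    sq = transcript_squares(transcripts, bounds, size_um)
    gene_idx = transcripts.table["gene"].map({g: i for i, g in enumerate(genes)}).to_numpy()
    counts = sp.csr_matrix(
        (np.ones(len(sq), dtype=np.int64), (gene_idx, sq)),
        shape=(len(genes), grid.n_squares),
    )
    return grid, CountTable(genes=genes, units=grid.squares.index, counts=counts)


def _finalize_tissue(spec, rng, nuclei, cells, types) -> SyntheticTissue:
    genes = pd.Index([f"G{i:04d}" for i in range(spec.n_genes)])
    rates = _rates(spec)
    rows = []
    for nuc, cell, t in zip(nuclei, cells, types):
        centroid = np.array(nuc.centroid)
        mult = np.ones(spec.n_genes)
        for svg in spec.svg_genes:
            if svg.cell_type in (-1, t):
                mult[svg.gene] *= 1.0 + svg.effect * _field_value(svg.field, centroid, spec.arena)
        counts = rng.poisson(rates[t] * mult)
        total = int(counts.sum())
        if total == 0:
            continue
        pts = _place_transcripts(rng, cell.polygon, total)
        rows.append(
            pd.DataFrame(
                {
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "gene": np.repeat(genes.to_numpy(), counts),
                    "gold_cell": nuc.nucleus_id,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["x", "y", "gene", "gold_cell"]
    )
    transcripts = TranscriptTable(table=table)
    grid, square_counts = _bin_tissue(transcripts, genes, spec.arena)
    return SyntheticTissue(
        spec=spec,
        nuclei=nuclei,
        cells=cells,
        cell_types=np.asarray(types),
        transcripts=transcripts,
        grid=grid,
        square_counts=square_counts,
        genes=genes,
    )


def generate_tissue(spec: TissueSpec) -> SyntheticTissue:
    """Sample a full synthetic tissue from a spec.

    Nuclei are random ellipses (16-point contours) rejected until the
    *whole-cell* polygons are pairwise disjoint, so the gold-standard
    transcript assignment is unambiguous.  Raises after 10^4 failed
    placement attempts (arena too small for the requested cell count).
    """
    rng = np.random.default_rng(spec.seed)
    margin = 0.08 * min(spec.arena)
    centers = rng.uniform(
        [margin, margin],
        [spec.arena[0] - margin, spec.arena[1] - margin],
        size=(spec.n_types, 2),
    )
    nuclei, cells, types = [], [], []
    attempts = 0
    scale = np.sqrt(spec.area_ratio)
    for i in range(spec.n_cells):
        t = i % spec.n_types
        while True:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError(
                    "could not place all cells without overlap; use a larger arena"
                )
            pos = np.clip(
                rng.normal(centers[t], spec.blob_sd),
                [margin, margin],
                [spec.arena[0] - margin, spec.arena[1] - margin],
            )
            area = float(
                np.exp(rng.normal(spec.nucleus_log_area_mean, spec.nucleus_log_area_sd))
            )
            nuc_poly = _ellipse(pos, area, rng.uniform(0.7, 1.0), rng.uniform(0, np.pi))
            c = nuc_poly.centroid
            xy = np.asarray(nuc_poly.exterior.coords)[:-1]
            cell_poly = Polygon(
                np.column_stack(
                    [scale * (xy[:, 0] - c.x) + c.x, scale * (xy[:, 1] - c.y) + c.y]
                )
            )
            if all(not cell_poly.intersects(prev.polygon) for prev in cells):
                break
        nuclei.append(NucleusPolygon(nucleus_id=i, polygon=nuc_poly))
        cells.append(NucleusPolygon(nucleus_id=i, polygon=cell_poly))
        types.append(t)
    return _finalize_tissue(spec, rng, nuclei, cells, types)


def generate_ideal_tissue(
    n_side: int = 4,
    cell_px: float = 12.0,
    gap_px: float = 4.0,
    n_genes: int = 30,
    n_types: int = 2,
    n_markers_per_type: int = 6,
    base_rate: float = 0.5,
    marker_rate: float = 4.0,
    seed: int = 0,
) -> SyntheticTissue:
    """The nested-lattice ideal tissue: every whole cell is an axis-aligned
    square built from whole 2 µm squares, the nucleus is the cell scaled by
    1/sqrt(2) about its center (so the expanded nucleus reproduces the cell
    exactly), and transcripts fall strictly inside cells.  Under these
    conditions nucleus-expansion assignment is exact.
    """
    if cell_px % 2 or gap_px % 2:
        raise ValueError("cell_px and gap_px must be multiples of the 2 µm pitch")
    pitch = cell_px + gap_px
    arena = (n_side * pitch + gap_px, n_side * pitch + gap_px)
    spec = TissueSpec(
        arena=arena,
        n_cells=n_side * n_side,
        n_types=n_types,
        n_genes=n_genes,
        n_markers_per_type=n_markers_per_type,
        base_rate=base_rate,
        marker_rate=marker_rate,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    nuclei, cells, types = [], [], []
    shrink = 1.0 / np.sqrt(2.0)
    i = 0
    for r in range(n_side):
        for c in range(n_side):
            x0 = gap_px + c * pitch
            y0 = gap_px + r * pitch
            cell_poly = Polygon(
                [(x0, y0), (x0 + cell_px, y0), (x0 + cell_px, y0 + cell_px), (x0, y0 + cell_px)]
            )
            cx, cy = x0 + cell_px / 2, y0 + cell_px / 2
            xy = np.asarray(cell_poly.exterior.coords)[:-1]
            nuc_poly = Polygon(
                np.column_stack(
                    [shrink * (xy[:, 0] - cx) + cx, shrink * (xy[:, 1] - cy) + cy]
                )
            )
            nuclei.append(NucleusPolygon(nucleus_id=i, polygon=nuc_poly))
            cells.append(NucleusPolygon(nucleus_id=i, polygon=cell_poly))
            types.append(i % n_types)
            i += 1
    # shrink transcript support slightly so points are strictly interior
    eps = 1e-6
    inner = [
        NucleusPolygon(p.nucleus_id, p.polygon.buffer(-eps, join_style="mitre"))
        for p in cells
    ]
    tissue = _finalize_tissue(spec, rng, nuclei, inner, types)
    return SyntheticTissue(
        spec=spec,
        nuclei=nuclei,
        cells=cells,
        cell_types=tissue.cell_types,
        transcripts=tissue.transcripts,
        grid=tissue.grid,
        square_counts=tissue.square_counts,
        genes=tissue.genes,
    )


def generate_null(cells: CellMatrix, rng_seed: int = 0) -> CellMatrix:
    """Permute the coordinate *pairs* across cells; expression untouched."""
    if cells.n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(cells.n_cells)
    meta = cells.cells.copy()
    meta[["x", "y"]] = cells.coords[perm]
    return CellMatrix(genes=cells.genes, cells=meta, counts=cells.counts.copy(), labels=cells.labels)


def _standardized_field(kind: str, coords: np.ndarray, arena) -> np.ndarray:
    vals = np.array([_field_value(kind, xy, arena) for xy in coords])
    sd = vals.std(ddof=1)
    return (vals - vals.mean()) / (sd if sd > 0 else 1.0)


def generate_svg_expression(
    coords: np.ndarray,
    n_svg: int = 50,
    n_null: int = 200,
    effect: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    field: str = "linear",
):
    """Continuous expression with planted SVGs on given coordinates.

    SVG genes are ``effect x field(s) + N(0, noise_sd^2)`` with the field
    standardized to unit sd across cells (so effect/noise_sd is the planted
    signal-to-noise ratio); null genes are noise only.  Returns
    ``(expression genes x cells, is_svg flags, gene names)``.
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arena = (coords[:, 0].max() - coords[:, 0].min() or 1.0, coords[:, 1].max() - coords[:, 1].min() or 1.0)
    rel = coords - coords.min(axis=0)
    kinds = ["linear", "radial"] if field == "mixed" else [field]
    expr = np.empty((n_svg + n_null, n))
    for g in range(n_svg):
        f = _standardized_field(kinds[g % len(kinds)], rel, arena)
        expr[g] = effect * f + rng.normal(0, noise_sd, n)
    expr[n_svg:] = rng.normal(0, noise_sd, (n_null, n))
    truth = np.zeros(n_svg + n_null, dtype=bool)
    truth[:n_svg] = True
    names = pd.Index(
        [f"SVG{i:04d}" for i in range(n_svg)] + [f"NULL{i:04d}" for i in range(n_null)]
    )
    return expr, truth, names


def generate_labeled_cells(
    n_cells: int = 600,
    n_genes: int = 500,
    n_types: int = 2,
    n_markers: int = 50,
    base_rate: float = 0.2,
    abundance_log_sd: float = 1.5,
    marker_fold: float = 8.0,
    dispersion: float = 0.5,
    arena: float = 300.0,
    seed: int = 0,
) -> CellMatrix:
    """Count matrix with planted cell types and spatially blobbed coordinates.

    Gene baseline abundances are log-normal around ``base_rate`` with sd
    ``abundance_log_sd`` on the log scale, so the panel spans high-abundance
    genes down to genes detected in only a few percent of cells, as in real
    UMI data; each type's block of ``n_markers`` genes is boosted
    ``marker_fold``-fold.  Counts are negative-binomial (gamma-Poisson,
    var = mu + dispersion * mu^2).  Coordinates come from per-type Gaussian
    blobs; ground-truth types are stored in ``labels``.
    """
    rng = np.random.default_rng(seed)
    types = np.arange(n_cells) % n_types
    abundance = np.clip(
        np.exp(rng.normal(np.log(base_rate), abundance_log_sd, n_genes)), 0.01, 5.0
    )
    rates = np.tile(abundance, (n_types, 1))
    for t in range(n_types):
        lo = t * n_markers
        hi = min(lo + n_markers, n_genes)
        rates[t, lo:hi] = np.maximum(rates[t, lo:hi] * marker_fold, 1.0)
    mu = rates[types]  # cells x genes
    if dispersion > 0:
        mu = mu * rng.gamma(1.0 / dispersion, dispersion, size=mu.shape)
    counts = rng.poisson(mu).astype(np.int64).T  # genes x cells
    centers = rng.uniform(0.25 * arena, 0.75 * arena, size=(n_types, 2))
    coords = np.clip(
        centers[types] + rng.normal(0, arena / 6, size=(n_cells, 2)), 0, arena
    )
    meta = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1]},
        index=pd.Index([f"c{i:05d}" for i in range(n_cells)], name="cell"),
    )
    return CellMatrix(
        genes=pd.Index([f"G{i:04d}" for i in range(n_genes)]),
        cells=meta,
        counts=sp.csr_matrix(counts),
        labels=types,
    )
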