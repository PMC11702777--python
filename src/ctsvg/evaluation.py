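"""Benchmarking square-to-cell assignment against gold-standard segmentation.

Xenium-style inputs — per-transcript coordinates with a gold-standard cell
id (point-in-whole-cell-boundary) plus nucleus and whole-cell polygons — are
converted into a synthetic 2 µm lattice; the nucleus-expansion assignment is
compared with the 8 µm-binning baseline on three metrics: transcript mapping
accuracy, median across-gene correlation of per-cell expression, and
adjusted Rand index of downstream cell clusterings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.strtree import STRtree
from sklearn.metrics import adjusted_rand_score

from .assignment import _subsquare_offsets, assign_cells
from .containers import (
    UNASSIGNED,
    CellMatrix,
    CountTable,
    NucleusPolygon,
    SquareGrid,
    TranscriptTable,
)
from .preprocessing import lognormalize, reduce_and_cluster

logger = logging.getLogger(__name__)

CONTROL_PREFIXES = ("NegControlProbe", "NegControlCodeword", "UnassignedCodeword")


def subset_rectangle(
    transcripts: TranscriptTable,
    nuclei: list[NucleusPolygon],
    cells_gold: list[NucleusPolygon],
    frac: float = 0.2,
):
    """Central rectangle subset: width/height = ``frac`` x the data bounding box.

    Cells whose nucleus centroid lies inside the rectangle are kept (with
    their whole-cell polygons); transcripts are kept when they fall inside
    the rectangle.
    """
    if frac <= 0:
        raise ValueError("frac must be positive")
    xy = transcripts.coords
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    # tiny relative margin so frac = 1 keeps boundary points despite rounding
    eps = 1.0 + 1e-12
    hw, hh = eps * frac * (xmax - xmin) / 2, eps * frac * (ymax - ymin) / 2
    lo = (cx - hw, cy - hh)
    hi = (cx + hw, cy + hh)

    def _in_rect(px, py):
        return (lo[0] <= px) & (px <= hi[0]) & (lo[1] <= py) & (py <= hi[1])

    keep_mask = _in_rect(xy[:, 0], xy[:, 1])
    sub_tr = TranscriptTable(table=transcripts.table.loc[keep_mask].reset_index(drop=True))
    kept_ids = {
        n.nucleus_id for n in nuclei if _in_rect(n.centroid[0], n.centroid[1])
    }
    sub_nuc = [n for n in nuclei if n.nucleus_id in kept_ids]
    sub_cells = [c for c in cells_gold if c.nucleus_id in kept_ids]
    if len(sub_tr) == 0 or not sub_nuc:
        raise ValueError("empty rectangle subset")
    return sub_tr, sub_nuc, sub_cells


def drop_controls(transcripts: TranscriptTable) -> TranscriptTable:
    """Remove control-probe transcripts by gene-name prefix."""
    genes = transcripts.table["gene"].astype(str)
    mask = ~genes.str.startswith(CONTROL_PREFIXES)
    return TranscriptTable(table=transcripts.table.loc[mask].reset_index(drop=True))


def gridify(bounds, size_px: float) -> SquareGrid:
    """Axis-aligned half-open squares tiling the bounding box, anchored at its
    min corner.  ``bounds`` is (xmin, ymin, xmax, ymax)."""
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    xmin, ymin, xmax, ymax = map(float, bounds)
    ncol = max(1, int(np.ceil((xmax - xmin) / size_px - 1e-12)))
    nrow = max(1, int(np.ceil((ymax - ymin) / size_px - 1e-12)))
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    squares = pd.DataFrame(
        {
            "x": xmin + (cols + 0.5) * size_px,
            "y": ymin + (rows + 0.5) * size_px,
            "row": rows,
            "col": cols,
        },
        index=pd.Index([f"s{r:04d}_{c:04d}" for r, c in zip(rows, cols)]),
    )
    return SquareGrid(squares=squares, size_px=size_px)


def transcript_squares(transcripts: TranscriptTable, bounds, size_px: float) -> np.ndarray:
    """Row-major square index for every transcript on the anchored lattice."""
    xmin, ymin, xmax, ymax = map(float, bounds)
    grid = gridify(bounds, size_px)
    ncol = int(grid.squares["col"].max()) + 1
    xy = transcripts.coords
    col = np.floor((xy[:, 0] - xmin) / size_px).astype(int)
    row = np.floor((xy[:, 1] - ymin) / size_px).astype(int)
    return row * ncol + col


def bin_transcripts(transcripts: TranscriptTable, bounds, size_px: float):
    """Bin transcripts on the anchored lattice -> (SquareGrid, CountTable)."""
    grid = gridify(bounds, size_px)
    sq = transcript_squares(transcripts, bounds, size_px)
    genes = pd.Index(sorted(transcripts.table["gene"].unique()))
    gene_idx = transcripts.table["gene"].map({g: i for i, g in enumerate(genes)}).to_numpy()
    counts = sp.csr_matrix(
        (np.ones(len(sq), dtype=np.int64), (gene_idx, sq)),
        shape=(len(genes), grid.n_squares),
    )
    return grid, CountTable(genes=genes, units=grid.squares.index, counts=counts)


def bin8_baseline(cells_gold: list[NucleusPolygon], grid8: SquareGrid) -> dict[int, int]:
    """Map every whole cell to the single 8 µm square with the largest
    (subsquare-approximated) overlap; ties go to the smallest square index.
    A square may serve several cells."""
    size = grid8.size_px
    corners = grid8.corners()
    boxes = shapely.box(corners[:, 0], corners[:, 1], corners[:, 0] + size, corners[:, 1] + size)
    tree = STRtree(boxes)
    ox, oy = _subsquare_offsets(size)
    mapping: dict[int, int] = {}
    for cell in cells_gold:
        cand = np.sort(tree.query(cell.polygon))
        if cand.size == 0:
            continue
        px = (corners[cand, 0][:, None] + ox[None, :]).ravel()
        py = (corners[cand, 1][:, None] + oy[None, :]).ravel()
        inside = shapely.intersects_xy(cell.polygon, px, py).reshape(len(cand), -1)
        counts = inside.sum(axis=1)
        if counts.max() == 0:
            continue
        mapping[cell.nucleus_id] = int(cand[int(np.argmax(counts))])
    return mapping


def bin8_cell_counts(
    transcripts: TranscriptTable, cell_to_square: dict[int, int], square_of_transcript: np.ndarray
) -> CellMatrix:
    """Per-cell expression under the 8 µm baseline: each cell receives the
    transcripts of its assigned square (shared squares double-count)."""
    genes = pd.Index(sorted(transcripts.table["gene"].unique()))
    gmap = {g: i for i, g in enumerate(genes)}
    gene_idx = transcripts.table["gene"].map(gmap).to_numpy()
    cells = sorted(cell_to_square)
    rows, cols = [], []
    for j, cid in enumerate(cells):
        mask = square_of_transcript == cell_to_square[cid]
        rows.append(gene_idx[mask])
        cols.append(np.full(int(mask.sum()), j))
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    counts = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(len(genes), len(cells))
    )
    meta = pd.DataFrame(index=pd.Index([str(c) for c in cells], name="cell"))
    meta["x"] = 0.0
    meta["y"] = 0.0
    return CellMatrix(genes=genes, cells=meta, counts=counts)


def resolve_bin8_transcripts(
    square_of_transcript: np.ndarray,
    cell_to_square: dict[int, int],
    rng_seed: int = 0,
) -> np.ndarray:
    """Single-valued transcript -> cell map for the 8 µm baseline.

    A square claimed by several cells is first given to one of them uniformly
    at random (seeded), then each transcript inherits its square's cell.
    """
    rng = np.random.default_rng(rng_seed)
    square_cells: dict[int, list[int]] = {}
    for cid, sq in sorted(cell_to_square.items()):
        square_cells.setdefault(sq, []).append(cid)
    square_owner = {
        sq: (cids[0] if len(cids) == 1 else int(rng.choice(cids)))
        for sq, cids in square_cells.items()
    }
    return np.array(
        [square_owner.get(sq, UNASSIGNED) for sq in square_of_transcript], dtype=np.int64
    )


def mapping_accuracy(predicted: np.ndarray, gold: np.ndarray) -> float:
    """Proportion of transcripts with matching assignment (same cell, or both
    unassigned)."""
    predicted = np.asarray(predicted)
    gold = np.asarray(gold)
    if predicted.shape != gold.shape:
        raise ValueError("transcript universes differ")
    return float(np.mean(predicted == gold))


def expression_agreement(
    method: CellMatrix,
    gold: CellMatrix,
    min_total: int = 10,
    scale_factor: float = 100.0,
    clip: float = 10.0,
) -> float:
    """Median per-cell Pearson correlation of scaled log-normalized expression.

    Cells shared by both matrices with >= ``min_total`` reads in each are
    compared gene-by-gene; zero-variance cells are excluded with a warning.
    """
    shared_genes = method.genes.intersection(gold.genes)

    def _prep(cm: CellMatrix) -> pd.DataFrame:
        totals = np.asarray(cm.counts.sum(axis=0)).ravel()
        keep = totals >= min_total
        sub = cm.subset_cells(keep)
        norm = np.asarray(lognormalize(sub, scale_factor=scale_factor).todense())
        mu = norm.mean(axis=1, keepdims=True)
        sd = norm.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        scaled = np.clip((norm - mu) / sd, -clip, clip)
        return pd.DataFrame(scaled, index=cm.genes, columns=sub.cells.index).loc[shared_genes]

    a, b = _prep(method), _prep(gold)
    shared = a.columns.intersection(b.columns)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared cells")
    cors = []
    for cell in shared:
        x, y = a[cell].to_numpy(), b[cell].to_numpy()
        if x.std() == 0 or y.std() == 0:
            logger.warning("cell %s has zero variance across genes; excluded", cell)
            continue
        cors.append(np.corrcoef(x, y)[0, 1])
    return float(np.median(cors))


def clustering_agreement(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two cell partitions."""
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

def gold_cell_matrix(transcripts: TranscriptTable, nuclei: list[NucleusPolygon]) -> CellMatrix:
    """Gold-standard per-cell counts from the transcript table's cell ids."""
    genes = pd.Index(sorted(transcripts.table["gene"].unique()))
    gmap = {g: i for i, g in enumerate(genes)}
    by_id = {n.nucleus_id: n for n in nuclei}
    assigned = transcripts.table[transcripts.table["gold_cell"] != UNASSIGNED]
    cells = sorted(set(assigned["gold_cell"]) & set(by_id))
    cmap = {c: j for j, c in enumerate(cells)}
    sub = assigned[assigned["gold_cell"].isin(cmap)]
    counts = sp.csr_matrix(
        (
            np.ones(len(sub), dtype=np.int64),
            (sub["gene"].map(gmap).to_numpy(), sub["gold_cell"].map(cmap).to_numpy()),
        ),
        shape=(len(genes), len(cells)),
    )
    meta = pd.DataFrame(
        {
            "x": [by_id[c].centroid[0] for c in cells],
            "y": [by_id[c].centroid[1] for c in cells],
        },
        index=pd.Index([str(c) for c in cells], name="cell"),
    )
    return CellMatrix(genes=genes, cells=meta, counts=counts)


def _cluster_for_eval(cm: CellMatrix, min_total: int, resolution: float, seed: int):
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    sub = cm.subset_cells(totals >= min_total)
    norm = lognormalize(sub, scale_factor=100.0)
    n_pcs = min(10, min(norm.shape) - 1)
    labels = reduce_and_cluster(norm, n_pcs=n_pcs, resolution=resolution, seed=seed)
    return pd.Series(labels.labels, index=sub.cells.index)


def evaluate_tissue(
    transcripts: TranscriptTable,
    nuclei: list[NucleusPolygon],
    cells_gold: list[NucleusPolygon],
    size_um: float = 2.0,
    bin8_um: float = 8.0,
    area_ratio: float = 2.0,
    resolution: float = 1.0,
    rng_seed: int = 0,
    bounds=None,
) -> pd.DataFrame:
    """Run both assignment strategies on one tissue and score them.

    ``bounds`` fixes the lattice frame (xmin, ymin, xmax, ymax); by default
    it is derived from the transcript bounding box.  Returns a DataFrame
    indexed by method (``ctsvg``, ``bin8``) with columns ``accuracy``,
    ``correlation``, ``ari``.
    """
    transcripts = drop_controls(transcripts)
    xy = transcripts.coords
    if bounds is None:
        pad = 1e-9
        bounds = (
            xy[:, 0].min() - pad,
            xy[:, 1].min() - pad,
            xy[:, 0].max() + size_um,
            xy[:, 1].max() + size_um,
        )
    gold = transcripts.table["gold_cell"].to_numpy()

    # ctSVG route: 2 µm lattice, nucleus-expansion assignment
    grid2, counts2 = bin_transcripts(transcripts, bounds, size_um)
    cells_ct, assignment = assign_cells(grid2, counts2, nuclei, area_ratio=area_ratio)
    retained = set(int(c) for c in cells_ct.cells.index)
    sq2 = transcript_squares(transcripts, bounds, size_um)
    cell_of_square = assignment.cell
    pred_ct = np.array(
        [c if c in retained else UNASSIGNED for c in cell_of_square[sq2]], dtype=np.int64
    )

    # bin8 route: 8 µm lattice, cell -> argmax-overlap square
    grid8 = gridify(bounds, bin8_um)
    c2s = bin8_baseline(cells_gold, grid8)
    sq8 = transcript_squares(transcripts, bounds, bin8_um)
    pred_b8 = resolve_bin8_transcripts(sq8, c2s, rng_seed=rng_seed)
    cells_b8 = bin8_cell_counts(transcripts, c2s, sq8)

    gold_cm = gold_cell_matrix(transcripts, nuclei)
    gold_labels = _cluster_for_eval(gold_cm, 10, resolution, rng_seed)

    rows = {}
    for name, pred, cm in (("ctsvg", pred_ct, cells_ct), ("bin8", pred_b8, cells_b8)):
        labels = _cluster_for_eval(cm, 10, resolution, rng_seed)
        shared = labels.index.intersection(gold_labels.index)
        rows[name] = {
            "accuracy": mapping_accuracy(pred, gold),
            "correlation": expression_agreement(cm, gold_cm),
            "ari": clustering_agreement(labels.loc[shared], gold_labels.loc[shared]),
        }
    return pd.DataFrame(rows).T
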