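"""Nucleus-based assignment of 2 µm squares to cells.

The pipeline: (1) drop abnormally large nuclei on the log-area scale; (2)
assign each square to the nucleus with the largest approximate overlap,
where overlap is approximated by splitting the square into a 10 x 10 lattice
of subsquares and counting subsquare centroids falling inside the polygon;
(3) expand every retained nucleus about its centroid so its area reaches a
target multiple (default 2x) of the nucleus area, approximating the whole
cell; (4) assign the squares still unassigned to the expanded polygons the
same way; (5) remove abnormal cells (no squares, too little covered area, or
a disconnected square set); (6) aggregate square counts per cell.
"""

from __future__ import annotations

import logging
import math
from collections import deque

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from .containers import (
    STAGE_EXPANDED,
    STAGE_NUCLEUS,
    UNASSIGNED,
    CellMatrix,
    CountTable,
    NucleusPolygon,
    SquareAssignment,
    SquareGrid,
)

logger = logging.getLogger(__name__)

N_SUBSQUARES_PER_SIDE = 10


def filter_large_nuclei(nuclei: list[NucleusPolygon]) -> list[NucleusPolygon]:
    """Drop nuclei whose log area exceeds mean(log areas) + 2 sd(log areas).

    Natural log; sample standard deviation (n-1 denominator).  A single
    nucleus is retained with a warning since the sd is undefined.
    """
    if not nuclei:
        raise ValueError("no nuclei provided")
    if len(nuclei) == 1:
        logger.warning("single nucleus: size filter skipped (sd undefined)")
        return list(nuclei)
    log_areas = np.log([n.area for n in nuclei])
    cutoff = log_areas.mean() + 2.0 * log_areas.std(ddof=1)
    # tolerance keeps equal-area nuclei (sd = 0 up to float jitter) intact
    tol = 1e-9 * max(1.0, abs(cutoff))
    return [n for n, la in zip(nuclei, log_areas) if la <= cutoff + tol]


def _subsquare_offsets(size: float) -> tuple[np.ndarray, np.ndarray]:
    """Centroid offsets of the 10x10 subsquares relative to the square's min corner."""
    step = size / N_SUBSQUARES_PER_SIDE
    centers = (np.arange(N_SUBSQUARES_PER_SIDE) + 0.5) * step
    ox, oy = np.meshgrid(centers, centers)
    return ox.ravel(), oy.ravel()


def approximate_overlap(square_center, size: float, polygon: Polygon) -> float:
    """Approximate square/polygon overlap area by subsquare-centroid counting.

    Returns (number of subsquare centroids inside the polygon) x size^2 / 100.
    Points exactly on the polygon boundary count as inside.
    """
    cx, cy = float(square_center[0]), float(square_center[1])
    ox, oy = _subsquare_offsets(size)
    inside = shapely.intersects_xy(polygon, cx - size / 2 + ox, cy - size / 2 + oy)
    return float(inside.sum()) * size * size / (N_SUBSQUARES_PER_SIDE**2)


def assign_squares(
    grid: SquareGrid,
    polygons: list[NucleusPolygon],
    existing: SquareAssignment | None = None,
    stage: int = STAGE_NUCLEUS,
) -> SquareAssignment:
    """Assign currently unassigned squares to the argmax-overlap polygon.

    Squares already assigned in ``existing`` are never touched (second-pass
    monotonicity).  Ties on the subsquare count are broken by the smallest
    nucleus id; zero overlap leaves the square unassigned.
    """
    assignment = existing if existing is not None else SquareAssignment.empty(grid.squares.index)
    if len(assignment.square_ids) != grid.n_squares:
        raise ValueError("assignment does not match grid")
    if not polygons:
        return assignment
    ids = np.array([p.nucleus_id for p in polygons], dtype=np.int64)
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate nucleus ids")

    size = grid.size_px
    corners = grid.corners()
    open_idx = np.flatnonzero(~assignment.assigned_mask)
    if open_idx.size == 0:
        return assignment
    ox, oy = _subsquare_offsets(size)

    boxes = shapely.box(
        corners[open_idx, 0],
        corners[open_idx, 1],
        corners[open_idx, 0] + size,
        corners[open_idx, 1] + size,
    )
    tree = STRtree(boxes)

    n_open = open_idx.size
    best_count = np.zeros(n_open, dtype=np.int64)
    best_id = np.full(n_open, np.iinfo(np.int64).max, dtype=np.int64)
    best_cell = np.full(n_open, UNASSIGNED, dtype=np.int64)

    for poly in polygons:
        cand = tree.query(poly.polygon)
        if cand.size == 0:
            continue
        sq = open_idx[cand]
        px = (corners[sq, 0][:, None] + ox[None, :]).ravel()
        py = (corners[sq, 1][:, None] + oy[None, :]).ravel()
        inside = shapely.intersects_xy(poly.polygon, px, py).reshape(len(sq), -1)
        counts = inside.sum(axis=1)
        for local, c in zip(cand, counts):
            if c == 0:
                continue
            if c > best_count[local] or (c == best_count[local] and poly.nucleus_id < best_id[local]):
                best_count[local] = c
                best_id[local] = poly.nucleus_id
                best_cell[local] = poly.nucleus_id

    hit = best_cell != UNASSIGNED
    assignment.cell[open_idx[hit]] = best_cell[hit]
    assignment.stage[open_idx[hit]] = stage
    return assignment


def expand_nucleus(
    nucleus: NucleusPolygon, area_ratio: float = 2.0, literal_ratio_scaling: bool = False
) -> NucleusPolygon:
    """Scale a nucleus contour about its centroid to a target area multiple.

    Each vertex maps to ``s (x_i - x0) + x0``, ``s (y_i - y0) + y0``.  With the
    default ``s = sqrt(area_ratio)`` this is a similarity transform whose image
    has exactly ``area_ratio`` times the original area.  With
    ``literal_ratio_scaling=True`` the linear factor is the area ratio itself
    (compatibility behaviour; the resulting area is ``area_ratio^2`` times the
    original).
    """
    if area_ratio < 1:
        raise ValueError("area_ratio must be >= 1")
    s = area_ratio if literal_ratio_scaling else math.sqrt(area_ratio)
    x0, y0 = nucleus.centroid
    xy = nucleus.contour
    scaled = np.empty_like(xy)
    scaled[:, 0] = s * (xy[:, 0] - x0) + x0
    scaled[:, 1] = s * (xy[:, 1] - y0) + y0
    return NucleusPolygon(nucleus_id=nucleus.nucleus_id, polygon=Polygon(scaled))


def _connected(cells_rc: np.ndarray) -> bool:
    """True iff the (row, col) lattice positions form one 4-connected component."""
    if len(cells_rc) <= 1:
        return True
    todo = {tuple(rc) for rc in cells_rc}
    start = next(iter(todo))
    seen = {start}
    queue = deque([start])
    while queue:
        r, c = queue.popleft()
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in todo and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(todo)


def remove_abnormal_cells(
    assignment: SquareAssignment,
    grid: SquareGrid,
    nuclei: list[NucleusPolygon],
    expanded: list[NucleusPolygon],
    min_area_fraction: float = 0.5,
    use_expanded_area: bool = True,
) -> list[int]:
    """Retained cell ids after removing abnormal cells.

    A cell is abnormal when (a) it has no assigned squares, (b) the total area
    of its assigned squares is below ``min_area_fraction`` of its (expanded,
    by default) cell area, or (c) its squares are not a single 4-connected
    component on the (row, col) lattice.
    """
    area_by_id = {p.nucleus_id: p.area for p in (expanded if use_expanded_area else nuclei)}
    square_area = grid.size_px**2
    rc = grid.squares[["row", "col"]].to_numpy(dtype=np.int64)
    retained = []
    cell_ids = assignment.cell
    for poly in nuclei:
        cid = poly.nucleus_id
        idx = np.flatnonzero(cell_ids == cid)
        if idx.size == 0:
            continue  # rule (a)
        if idx.size * square_area < min_area_fraction * area_by_id[cid]:
            continue  # rule (b)
        if not _connected(rc[idx]):
            continue  # rule (c)
        retained.append(cid)
    return retained


def aggregate_counts(
    assignment: SquareAssignment,
    square_counts: CountTable,
    retained: list[int],
    nuclei: list[NucleusPolygon],
    expanded: list[NucleusPolygon] | None = None,
) -> CellMatrix:
    """Sum square counts per retained cell; the cell coordinate is the nucleus centroid."""
    if not square_counts.units.equals(pd.Index(assignment.square_ids)):
        raise ValueError("count table units do not match assignment squares")
    retained = sorted(retained)
    nuc_by_id = {p.nucleus_id: p for p in nuclei}
    exp_by_id = {p.nucleus_id: p for p in (expanded or [])}
    cell_pos = {cid: k for k, cid in enumerate(retained)}

    n_units = len(square_counts.units)
    rows, cols = [], []
    for j, cid in enumerate(assignment.cell):
        if cid in cell_pos:
            rows.append(j)
            cols.append(cell_pos[cid])
    agg = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n_units, len(retained))
    )
    counts = sp.csr_matrix(square_counts.counts @ agg)

    meta = pd.DataFrame(
        {
            "x": [nuc_by_id[c].centroid[0] for c in retained],
            "y": [nuc_by_id[c].centroid[1] for c in retained],
            "nucleus_area": [nuc_by_id[c].area for c in retained],
            "expanded_area": [
                exp_by_id[c].area if c in exp_by_id else np.nan for c in retained
            ],
            "n_squares": np.asarray(agg.sum(axis=0)).ravel().astype(np.int64),
        },
        index=pd.Index([str(c) for c in retained], name="cell"),
    )
    return CellMatrix(genes=square_counts.genes, cells=meta, counts=counts)


def assign_cells(
    grid: SquareGrid,
    square_counts: CountTable,
    nuclei: list[NucleusPolygon],
    area_ratio: float = 2.0,
    literal_ratio_scaling: bool = False,
) -> tuple[CellMatrix, SquareAssignment]:
    """Run the full square-to-cell pipeline and return the aggregated matrix.

    Stages: nucleus size filter, nucleus-overlap pass, centroid-anchored
    expansion to ``area_ratio`` times the nucleus area, expanded-overlap pass
    over the remaining squares, abnormal-cell removal, count aggregation.
    """
    kept = filter_large_nuclei(nuclei)
    assignment = assign_squares(grid, kept, stage=STAGE_NUCLEUS)
    expanded = [expand_nucleus(n, area_ratio, literal_ratio_scaling) for n in kept]
    assignment = assign_squares(grid, expanded, existing=assignment, stage=STAGE_EXPANDED)
    retained = remove_abnormal_cells(assignment, grid, kept, expanded)
    cells = aggregate_counts(assignment, square_counts, retained, kept, expanded)
    return cells, assignment
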