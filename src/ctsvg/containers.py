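"""Core in-memory containers shared across the pipeline.

All geometry lives in continuous full-resolution pixel coordinates with the
image convention: origin at the top-left, ``y`` increasing downward.  A 2 µm
square with center ``(cx, cy)`` and side ``s`` occupies the half-open region
``[cx - s/2, cx + s/2) x [cy - s/2, cy + s/2)`` so the lattice tiles the plane
without double-counting boundary points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import Polygon

UNASSIGNED = -1
#: stage flags for assigned squares
STAGE_NUCLEUS = 1
STAGE_EXPANDED = 2


@dataclass
class SquareGrid:
    """The 2 µm square lattice.

    ``squares`` is indexed by square id (barcode) with columns ``x``, ``y``
    (pixel center), ``row``, ``col`` (array lattice indices).
    """

    squares: pd.DataFrame
    size_px: float

    def __post_init__(self) -> None:
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")
        if self.squares.index.has_duplicates:
            raise ValueError("duplicate square ids")

    @property
    def n_squares(self) -> int:
        return len(self.squares)

    def corners(self) -> np.ndarray:
        """(n, 2) array of min-corner coordinates of each square."""
        half = self.size_px / 2.0
        return self.squares[["x", "y"]].to_numpy(dtype=float) - half


@dataclass
class NucleusPolygon:
    """A segmented nucleus contour.

    The contour is stored as a shapely polygon (exterior ring only); ``area``
    and ``centroid`` are derived from it via the shoelace formula.
    """

    nucleus_id: int
    polygon: Polygon

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (float(c.x), float(c.y))

    @property
    def contour(self) -> np.ndarray:
        """(N, 2) array of exterior-ring vertices (closing point dropped)."""
        xy = np.asarray(self.polygon.exterior.coords, dtype=float)
        return xy[:-1]


@dataclass
class CountTable:
    """Sparse non-negative integer counts, genes x units (squares or cells)."""

    genes: pd.Index
    units: pd.Index
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.units = pd.Index(self.units)
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.units.has_duplicates:
            raise ValueError("duplicate unit ids")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.units)):
            raise ValueError("counts shape does not match genes x units")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class CellMatrix:
    """Aggregated single-cell expression with spatial coordinates.

    ``counts`` is genes x cells (sparse); ``cells`` is indexed by cell id with
    at least columns ``x`` and ``y`` (nucleus centroid in pixels) and, when
    produced by square assignment, ``nucleus_area``, ``expanded_area`` and
    ``n_squares``.  ``labels`` holds optional integer cluster ids.
    """

    genes: pd.Index
    cells: pd.DataFrame
    counts: sp.csr_matrix
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.cells.index.has_duplicates:
            raise ValueError("duplicate cell ids")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match genes x cells")
        coords = self.coords
        if len(coords) and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite cell coordinates")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def subset_cells(self, mask_or_idx) -> "CellMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            genes=self.genes,
            cells=self.cells.iloc[idx].copy(),
            counts=sp.csr_matrix(self.counts[:, idx]),
            labels=None if self.labels is None else np.asarray(self.labels)[idx],
        )

    def subset_genes(self, mask_or_idx) -> "CellMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellMatrix(
            genes=self.genes[idx],
            cells=self.cells.copy(),
            counts=sp.csr_matrix(self.counts[idx]),
            labels=self.labels,
        )

    def to_anndata(self):
        """Cells x genes AnnData view for scanpy-based steps."""
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts.T),
            obs=self.cells.copy(),
            var=pd.DataFrame(index=self.genes),
        )
        adata.obsm["spatial"] = self.coords
        if self.labels is not None:
            adata.obs["cluster"] = pd.Categorical(np.asarray(self.labels))
        return adata


@dataclass
class TranscriptTable:
    """Per-transcript coordinates, gene symbol and gold-standard cell id.

    ``gold_cell`` uses :data:`UNASSIGNED` (= -1) for transcripts outside every
    whole-cell boundary.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"x", "y", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"transcript table missing columns: {sorted(missing)}")
        if "gold_cell" not in self.table.columns:
            self.table = self.table.assign(gold_cell=UNASSIGNED)
        if (self.table["gene"].astype(str) == "").any():
            raise ValueError("empty gene symbol in transcript table")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)


@dataclass
class SquareAssignment:
    """Square -> cell map with the assignment stage per square.

    ``cell`` and ``stage`` are aligned with ``square_ids``; unassigned squares
    carry :data:`UNASSIGNED` / stage 0.
    """

    square_ids: pd.Index
    cell: np.ndarray
    stage: np.ndarray

    @classmethod
    def empty(cls, square_ids: pd.Index) -> "SquareAssignment":
        n = len(square_ids)
        return cls(
            square_ids=pd.Index(square_ids),
            cell=np.full(n, UNASSIGNED, dtype=np.int64),
            stage=np.zeros(n, dtype=np.int8),
        )

    @property
    def assigned_mask(self) -> np.ndarray:
        return self.cell != UNASSIGNED

    def to_frame(self) -> pd.DataFrame:
        stage_names = np.array(["unassigned", "nucleus", "expanded"])
        return pd.DataFrame(
            {"cell": self.cell, "stage": stage_names[self.stage]},
            index=self.square_ids,
        )
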