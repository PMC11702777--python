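import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from shapely.geometry import Polygon

from ctsvg.containers import CountTable, NucleusPolygon, SquareGrid


def make_grid(nrow: int, ncol: int, size: float = 2.0, origin=(0.0, 0.0)) -> SquareGrid:
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    squares = pd.DataFrame(
        {
            "x": origin[0] + (cols + 0.5) * size,
            "y": origin[1] + (rows + 0.5) * size,
            "row": rows,
            "col": cols,
        },
        index=pd.Index([f"sq_{r}_{c}" for r, c in zip(rows, cols)]),
    )
    return SquareGrid(squares=squares, size_px=size)


def make_counts(grid: SquareGrid, dense: np.ndarray, genes=None) -> CountTable:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    return CountTable(
        genes=pd.Index(genes), units=grid.squares.index, counts=sp.csr_matrix(dense)
    )


def square_nucleus(nucleus_id: int, center, area: float) -> NucleusPolygon:
    """Axis-aligned square polygon with an exact target area."""
    half = np.sqrt(area) / 2.0
    x, y = center
    return NucleusPolygon(
        nucleus_id=nucleus_id,
        polygon=Polygon(
            [(x - half, y - half), (x + half, y - half), (x + half, y + half), (x - half, y + half)]
        ),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def blob_expression():
    """Two well-separated expression blobs: (normalized genes x cells, labels)."""
    gen = np.random.default_rng(7)
    n_per, n_genes = 100, 30
    a = gen.normal(0.0, 0.5, size=(n_per, n_genes))
    b = gen.normal(0.0, 0.5, size=(n_per, n_genes))
    a[:, : n_genes // 2] += 4.0
    b[:, n_genes // 2 :] += 4.0
    X = np.vstack([a, b]).T  # genes x cells
    labels = np.repeat([0, 1], n_per)
    return sp.csr_matrix(X), labels
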