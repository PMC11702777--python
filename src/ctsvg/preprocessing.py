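"""QC, log-normalization, dimension reduction and seeded graph clustering.

Mirrors a standard single-cell workflow: cells with too few detected genes
are dropped, then genes detected in too small a fraction of the retained
cells; counts are library-size log-normalized; highly variable genes are
selected; scaled expression (clipped at 10) feeds a PCA; a kNN graph over
the top PCs is partitioned with Louvain community detection at a fixed
resolution.  Clustering is a pure function of (matrix, parameters, seed),
which the statistical testing stage relies on when it re-runs community
detection under seeds 1..1000.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CellMatrix


@dataclass
class ClusterLabels:
    """Per-cell integer cluster ids (contiguous from 0) with their provenance."""

    labels: np.ndarray
    seed: int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def qc_filter(
    cells: CellMatrix, min_genes: int = 300, min_cell_frac: float = 0.01
) -> CellMatrix:
    """Keep cells detecting >= ``min_genes`` genes, then genes positive in
    >= ``min_cell_frac`` of the retained cells (count >= frac * n, no rounding)."""
    genes_per_cell = np.asarray((cells.counts > 0).sum(axis=0)).ravel()
    keep_cells = genes_per_cell >= min_genes
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    out = cells.subset_cells(keep_cells)
    cells_per_gene = np.asarray((out.counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cell_frac * out.n_cells
    return out.subset_genes(keep_genes)


def lognormalize(cells: CellMatrix, scale_factor: float = 1e4) -> sp.csr_matrix:
    """ln(1 + count / cell_total * scale_factor), sparse genes x cells.

    Zeros are preserved; a zero-total cell is an error (impossible after QC).
    """
    totals = np.asarray(cells.counts.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        raise ValueError("cell with zero total counts")
    norm = cells.counts.tocsc(copy=True).astype(float)
    norm.data *= np.repeat(scale_factor / totals, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    return norm.tocsr()


def _select_hvg(normalized: sp.csr_matrix, n_top: int) -> np.ndarray:
    """Dispersion-based highly-variable-gene mask on log data (Seurat flavor)."""
    import anndata as ad
    import scanpy as sc

    n_genes = normalized.shape[0]
    if n_genes <= n_top:
        return np.ones(n_genes, dtype=bool)
    adata = ad.AnnData(X=sp.csr_matrix(normalized.T))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    return adata.var["highly_variable"].to_numpy()


def _scale_rows(dense: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Per-gene z-score (sample sd) with values clipped at ``clip``."""
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return np.clip((dense - mu) / sd, -clip, clip)


class GraphClustering:
    """Cached embedding + kNN graph supporting cheap re-seeded Louvain runs.

    The PCA embedding and the neighbour graph are deterministic functions of
    the input, so re-clustering under a new seed only re-runs community
    detection; this is what makes the 1000-seed reassignment step affordable.
    """

    def __init__(
        self,
        normalized: sp.csr_matrix,
        n_pcs: int = 10,
        n_neighbors: int = 20,
        n_hvg: int = 2000,
        resolution: float = 1.2,
    ):
        n_genes, n_cells = normalized.shape
        if n_cells < 2:
            raise ValueError("need at least 2 cells to cluster")
        hvg = _select_hvg(normalized, n_hvg)
        dense = np.asarray(normalized[hvg].todense(), dtype=float)
        scaled = _scale_rows(dense)
        max_pcs = min(n_cells, scaled.shape[0]) - 1
        if n_pcs > max_pcs:
            raise ValueError(f"n_pcs={n_pcs} exceeds min(n_cells, n_genes) - 1 = {max_pcs}")
        self.resolution = resolution
        self.hvg_mask = hvg
        self.embedding = PCA(n_components=n_pcs, svd_solver="full").fit_transform(scaled.T)

        k = min(n_neighbors, n_cells - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(self.embedding)
        _, idx = nn.kneighbors(self.embedding)
        src = np.repeat(np.arange(n_cells), k)
        dst = idx[:, 1:].ravel()
        edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
        self.graph = igraph.Graph(n=n_cells, edges=sorted(edges))

    def cluster(self, seed: int, resolution: float | None = None) -> np.ndarray:
        """Louvain labels under ``seed``, relabelled by decreasing cluster size."""
        res = self.resolution if resolution is None else resolution
        random.seed(seed)
        membership = np.asarray(
            self.graph.community_multilevel(resolution=res).membership
        )
        ids, counts = np.unique(membership, return_counts=True)
        order = ids[np.lexsort((ids, -counts))]
        remap = {old: new for new, old in enumerate(order)}
        return np.array([remap[m] for m in membership], dtype=np.int64)


def reduce_and_cluster(
    normalized: sp.csr_matrix,
    n_pcs: int = 10,
    resolution: float = 1.2,
    seed: int = 0,
    n_neighbors: int = 20,
    n_hvg: int = 2000,
) -> ClusterLabels:
    """HVG -> scale -> PCA -> kNN graph -> seeded Louvain, in one call."""
    gc = GraphClustering(
        normalized,
        n_pcs=n_pcs,
        n_neighbors=n_neighbors,
        n_hvg=n_hvg,
        resolution=resolution,
    )
    return ClusterLabels(labels=gc.cluster(seed), seed=seed, resolution=resolution)
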