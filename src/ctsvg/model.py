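"""Model/results interface for cell-type-specific SVG detection.

``SpatialSVG`` is constructed from an aggregated single-cell matrix with
cluster labels; ``fit()`` runs the per-cluster spatial filtering and the
shared-design tensor B-spline regression and returns ``SpatialSVGResults``,
which carries per-gene F statistics, fitted surfaces, and — after
``test()`` — permutation-calibrated p-values, Gamma parameters and BH FDRs,
exposed through ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellMatrix
from .preprocessing import GraphClustering, lognormalize
from .spline import (
    BatchFit,
    build_design,
    filter_cluster_genes,
    fit_genes,
    isolation_mask,
    standardize_fits,
)
from .testing import (
    Reassignment,
    adjust_bh,
    build_reassignments,
    gamma_pvalues,
    null_statistics,
    parametric_pvalue_baseline,
)

logger = logging.getLogger(__name__)


@dataclass
class ClusterFit:
    """Observed fit for one cluster: retained cells/genes, design and statistics."""

    cluster: int
    cell_idx: np.ndarray          # indices into the model's cell universe
    gene_idx: np.ndarray          # indices into the model's gene universe
    fit: BatchFit

    @property
    def n_cells(self) -> int:
        return len(self.cell_idx)


class SpatialSVG:
    """Spatial spline-regression model for cell-type-specific SVGs.

    Parameters
    ----------
    cells
        Aggregated single-cell counts with coordinates; ``labels`` falls back
        to ``cells.labels``.
    n_knots
        Internal knots K per spatial dimension (p = 1 + 2(K+3) + (K+3)^2
        design columns).
    min_gene_frac
        Per-cluster detection threshold: genes positive in at least this
        fraction of the cluster's retained cells are tested.
    normalized
        Optional precomputed log-normalized matrix (genes x cells); computed
        with scale factor 1e4 when omitted.
    """

    def __init__(
        self,
        cells: CellMatrix,
        labels: Optional[np.ndarray] = None,
        n_knots: int = 2,
        min_gene_frac: float = 0.01,
        normalized=None,
        min_residual_df: int = 10,
    ):
        self.cells = cells
        labels = cells.labels if labels is None else labels
        if labels is None:
            raise ValueError("cluster labels required (run reduce_and_cluster first)")
        self.labels = np.asarray(labels)
        if len(self.labels) != cells.n_cells:
            raise ValueError("labels length does not match cells")
        self.n_knots = n_knots
        self.min_gene_frac = min_gene_frac
        self.min_residual_df = min_residual_df
        if normalized is None:
            normalized = lognormalize(cells)
        self.normalized = (
            normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized, float)
        )

    @classmethod
    def from_anndata(cls, adata, cluster_key: str = "cluster", **kwargs) -> "SpatialSVG":
        """Build from a cells x genes AnnData with coordinates in obsm['spatial']."""
        coords = np.asarray(adata.obsm["spatial"])
        cells = CellMatrix(
            genes=pd.Index(adata.var_names),
            cells=pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]}, index=adata.obs_names),
            counts=sp.csr_matrix(adata.X.T),
        )
        labels = np.asarray(adata.obs[cluster_key].cat.codes if hasattr(adata.obs[cluster_key], "cat") else adata.obs[cluster_key])
        return cls(cells, labels=labels, **kwargs)

    def fit(self) -> "SpatialSVGResults":
        """Per cluster: isolation-filter cells, filter genes, fit every gene.

        Clusters too small for the design are skipped with a warning; the F
        statistic needs a minimum residual degree-of-freedom margin
        (``min_residual_df``, default 10) beyond the n > p requirement to be
        numerically meaningful.
        """
        coords = self.cells.coords
        q = self.n_knots + 3
        p_nominal = 1 + 2 * q + q * q
        cluster_fits: dict[int, ClusterFit] = {}
        for c in np.unique(self.labels):
            idx = np.flatnonzero(self.labels == c)
            idx = idx[isolation_mask(coords[idx])]
            if len(idx) < p_nominal + self.min_residual_df:
                logger.warning(
                    "cluster %s skipped: %d cells < p + min_residual_df = %d",
                    c,
                    len(idx),
                    p_nominal + self.min_residual_df,
                )
                continue
            gene_mask = filter_cluster_genes(self.cells.counts[:, idx], self.min_gene_frac)
            gene_idx = np.flatnonzero(gene_mask)
            if gene_idx.size == 0:
                logger.warning("cluster %s: no genes pass the detection filter", c)
                continue
            try:
                design = build_design(coords[idx], self.n_knots)
            except ValueError as err:
                logger.warning("cluster %s skipped: %s", c, err)
                continue
            fit = fit_genes(design, self.normalized[np.ix_(gene_idx, idx)])
            cluster_fits[int(c)] = ClusterFit(
                cluster=int(c), cell_idx=idx, gene_idx=gene_idx, fit=fit
            )
        return SpatialSVGResults(model=self, cluster_fits=cluster_fits)


@dataclass
class SpatialSVGResults:
    """Fitted surfaces and test statistics; populated further by ``test()``."""

    model: SpatialSVG
    cluster_fits: dict[int, ClusterFit]
    nulls: dict[int, np.ndarray] = field(default_factory=dict)
    tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    reassignments: dict[int, list[Reassignment]] = field(default_factory=dict)

    def f_table(self, cluster: int) -> pd.DataFrame:
        cf = self.cluster_fits[cluster]
        return pd.DataFrame(
            {"gene": self.model.cells.genes[cf.gene_idx], "F": cf.fit.f_stat}
        )

    def standardized_fits(self, cluster: int, genes=None) -> pd.DataFrame:
        """Standardized fitted surfaces (genes x retained cells) for a cluster."""
        cf = self.cluster_fits[cluster]
        names = self.model.cells.genes[cf.gene_idx]
        df = pd.DataFrame(
            standardize_fits(cf.fit.fitted),
            index=names,
            columns=self.model.cells.cells.index[cf.cell_idx],
        )
        return df if genes is None else df.loc[genes]

    def test(
        self,
        clustering: GraphClustering,
        n_seeds: int = 1000,
        keep: int = 100,
        rng_seed: int = 0,
        fdr_cutoff: float = 0.05,
    ) -> "SpatialSVGResults":
        """Permutation test with clustering-uncertainty propagation.

        Re-seeds community detection ``n_seeds`` times on the cached graph,
        keeps the top-``keep`` Jaccard matches per cluster, generates null F
        statistics from coordinate-permuted reassigned clusters, fits a Gamma
        per gene and applies BH within each cluster.  The minimum usable null
        count is 30, relaxed to ``keep`` for reduced desk-scale runs.
        """
        min_nulls = min(30, keep)
        self.reassignments = build_reassignments(
            clustering, self.model.labels, n_seeds=n_seeds, keep=keep
        )
        coords = self.model.cells.coords
        for c, cf in self.cluster_fits.items():
            expr = self.model.normalized[cf.gene_idx]
            try:
                nulls = null_statistics(
                    expr,
                    coords,
                    self.reassignments[c],
                    n_knots=self.model.n_knots,
                    rng_seed=rng_seed + c,
                    min_nulls=min_nulls,
                )
            except RuntimeError as err:
                logger.warning("cluster %s: %s", c, err)
                continue
            self.nulls[c] = nulls
            p, shape, rate = gamma_pvalues(cf.fit.f_stat, nulls, min_nulls=min_nulls)
            fdr = adjust_bh(p)
            table = pd.DataFrame(
                {
                    "gene": self.model.cells.genes[cf.gene_idx],
                    "F": cf.fit.f_stat,
                    "p": p,
                    "fdr": fdr,
                    "gamma_shape": shape,
                    "gamma_rate": rate,
                    "significant": fdr <= fdr_cutoff,
                }
            )
            order = np.lexsort((-table["F"].to_numpy(), table["p"].to_numpy()))
            rank = np.empty(len(table), dtype=int)
            rank[order] = np.arange(1, len(table) + 1)
            table["rank"] = rank
            self.tables[c] = table.sort_values("rank").reset_index(drop=True)
        return self

    def parametric_baseline(self, cluster: int) -> pd.DataFrame:
        """F(p-1, n-p) tail p-values and BH FDRs, ignoring cluster uncertainty."""
        cf = self.cluster_fits[cluster]
        p = parametric_pvalue_baseline(cf.fit.f_stat, cf.fit.design.n, cf.fit.design.rank)
        return pd.DataFrame(
            {
                "gene": self.model.cells.genes[cf.gene_idx],
                "F": cf.fit.f_stat,
                "p": p,
                "fdr": adjust_bh(p),
            }
        )

    def summary(self, cluster: Optional[int] = None) -> pd.DataFrame:
        """Ranked per-gene table (gene, F, p, FDR, rank, significant).

        With ``cluster=None`` all tested clusters are concatenated with a
        ``cluster`` column; before ``test()`` only F statistics are available.
        """
        if cluster is not None:
            if cluster in self.tables:
                return self.tables[cluster].copy()
            return self.f_table(cluster).sort_values("F", ascending=False).reset_index(drop=True)
        frames = []
        for c in sorted(self.cluster_fits):
            df = self.summary(cluster=c)
            df.insert(0, "cluster", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)
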