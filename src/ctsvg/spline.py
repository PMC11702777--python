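"""Tensor-product cubic B-spline regression of expression on space.

For a cluster of n cells with coordinates ``(s_j1, s_j2)``, each gene's
log-normalized expression is modelled as

    y_ij = b0 + sum_k1 b1k1(s_j1) B_{k1,0} + sum_k2 b2k2(s_j2) B_{0,k2}
         + sum_k1 sum_k2 b1k1(s_j1) b2k2(s_j2) B_{k1,k2} + eps_ij,

where ``b_{d,1..K+3}`` are cubic B-spline basis functions with K equidistant
internal knots per dimension (the last K+3 of the K+4 clamped basis, so the
design is full rank alongside the explicit intercept).  The design matrix has
p = 1 + 2(K+3) + (K+3)^2 columns and is shared by every gene, so a single
orthogonal factorization serves the whole expression matrix; the overall
regression F statistic

    F_i = ((TSS_i - RSS_i) / (p - 1)) / (RSS_i / (n - p))

is the test statistic for spatial variability of gene i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.interpolate import BSpline
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spatial cell / gene filters
# ---------------------------------------------------------------------------

def isolation_k(n: int) -> int:
    """Neighbourhood size for the isolation score: round-half-up of 1% of n,
    clamped to [10, 50] and capped at n - 1."""
    k = int(np.floor(0.01 * n + 0.5))
    return max(1, min(max(10, min(50, k)), n - 1))


def isolation_scores(coords: np.ndarray) -> np.ndarray:
    """Mean Euclidean distance from each cell to its k nearest within-cluster cells."""
    n = len(coords)
    k = isolation_k(n)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return dist[:, 1:].mean(axis=1)


def isolation_mask(coords: np.ndarray, n_sd: float = 6.0) -> np.ndarray:
    """Boolean mask of cells retained by the spatial-isolation filter.

    Cells whose isolation score exceeds mean + ``n_sd`` sd across the cluster
    are dropped; with <= 1 cell the input is returned unchanged.
    """
    n = len(coords)
    if n <= 1:
        logger.warning("isolation filter skipped: %d cell(s)", n)
        return np.ones(n, dtype=bool)
    scores = isolation_scores(np.asarray(coords, dtype=float))
    cutoff = scores.mean() + n_sd * scores.std(ddof=1)
    return scores <= cutoff


def filter_cluster_genes(counts, min_frac: float = 0.01) -> np.ndarray:
    """Mask of genes positive in >= ``min_frac`` of the cluster's cells."""
    if sp.issparse(counts):
        pos = np.asarray((counts > 0).sum(axis=1)).ravel()
    else:
        pos = (np.asarray(counts) > 0).sum(axis=1)
    return pos >= min_frac * counts.shape[1]


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _bs_basis(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Cubic B-spline main-effect basis: the last K+3 columns of the clamped
    K+4 basis over [min(x), max(x)] with K equidistant internal knots (the
    dropped first column is absorbed by the model intercept)."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError("constant coordinate dimension")
    knots = np.concatenate(
        [[lo] * 4, np.linspace(lo, hi, n_knots + 2)[1:-1], [hi] * 4]
    )
    full = BSpline.design_matrix(x, knots, k=3).toarray()
    return full[:, 1:]


@dataclass
class SplineDesign:
    """Shared tensor B-spline design with a cached orthogonal factorization.

    ``p`` is the nominal column count 1 + 2(K+3) + (K+3)^2; when degenerate
    geometry makes basis columns collinear, dependent columns are dropped
    (logged) and ``rank`` is the effective count used in the F statistic.
    """

    coords: np.ndarray
    n_knots: int
    X: np.ndarray = field(init=False, repr=False)
    p: int = field(init=False)
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        n = len(coords)
        q = self.n_knots + 3
        self.p = 1 + 2 * q + q * q
        if n <= self.p:
            raise ValueError(
                f"n = {n} cells <= p = {self.p} design columns; reduce the knot count"
            )
        b1 = _bs_basis(coords[:, 0], self.n_knots)
        b2 = _bs_basis(coords[:, 1], self.n_knots)
        tensor = (b1[:, :, None] * b2[:, None, :]).reshape(n, q * q)  # row-major: k1 outer
        self.X = np.concatenate([np.ones((n, 1)), b1, b2, tensor], axis=1)

        # pivoted QR once; all genes reuse Q
        Q, R, piv = scipy.linalg.qr(self.X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag[0] * max(self.X.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < self.p:
            logger.warning(
                "design rank deficient: %d of %d columns independent; "
                "dependent columns dropped",
                rank,
                self.p,
            )
        self.rank = rank
        self._Q = Q[:, :rank]
        self._R = R[:rank, :rank]
        self._piv = piv[:rank]

    @property
    def basis_per_dim(self) -> int:
        return self.n_knots + 3

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(coords: np.ndarray, n_knots: int = 2) -> SplineDesign:
    """Assemble the shared design matrix for a cluster's cell coordinates."""
    return SplineDesign(coords=np.asarray(coords, dtype=float), n_knots=n_knots)


# ---------------------------------------------------------------------------
# batch least squares
# ---------------------------------------------------------------------------

@dataclass
class BatchFit:
    """Least-squares results for all genes of a cluster against one design.

    ``coef`` is (p x m) with rows in design-column order (dropped columns
    zero); ``fitted`` is (m x n); ``f_stat``, ``sigma2``, ``rss``, ``tss`` are
    per-gene vectors.
    """

    design: SplineDesign
    coef: np.ndarray
    fitted: np.ndarray
    rss: np.ndarray
    tss: np.ndarray
    sigma2: np.ndarray
    f_stat: np.ndarray


def fit_genes(design: SplineDesign, Y) -> BatchFit:
    """Fit every gene (rows of ``Y``, genes x cells) with the cached factorization.

    A constant gene (TSS = 0) gets F = 0 by convention; an exact fit
    (RSS = 0 with TSS > 0) gets F = inf.
    """
    Y = np.asarray(Y.todense() if sp.issparse(Y) else Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite expression values")
    if Y.shape[1] != design.n:
        raise ValueError("expression columns do not match design rows")
    n, p_eff = design.n, design.rank
    Yt = Y.T  # n x m
    qty = design._Q.T @ Yt  # rank x m
    fitted = design._Q @ qty  # n x m
    resid = Yt - fitted
    rss = np.einsum("ij,ij->j", resid, resid)
    centered = Yt - Yt.mean(axis=0, keepdims=True)
    tss = np.einsum("ij,ij->j", centered, centered)
    rss = np.minimum(rss, tss)  # guard sign of tiny numerical negatives

    df_num, df_den = p_eff - 1, n - p_eff
    sigma2 = rss / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df_num) / (rss / df_den)
    f = np.where(tss <= 0, 0.0, f)

    coef = np.zeros((design.p, Y.shape[0]))
    coef[design._piv] = scipy.linalg.solve_triangular(design._R, qty)
    return BatchFit(
        design=design,
        coef=coef,
        fitted=fitted.T,
        rss=rss,
        tss=tss,
        sigma2=sigma2,
        f_stat=np.asarray(f, dtype=float),
    )


def standardize_fits(fitted: np.ndarray) -> np.ndarray:
    """Standardize each gene's fitted surface to mean 0, sample sd 1 across cells.

    Constant surfaces map to all-zero (with a warning): they carry no spatial
    pattern to compare.
    """
    fitted = np.asarray(fitted, dtype=float)
    mu = fitted.mean(axis=1, keepdims=True)
    sd = fitted.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant fitted surface(s) standardized to zero", flat.sum())
    sd[sd == 0] = 1.0
    out = (fitted - mu) / sd
    out[flat] = 0.0
    return out
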