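"""Significance testing that propagates clustering uncertainty.

Because cell clusters are inferred from the expression data, the spatial-F
statistic's null distribution within a cluster is wider than the parametric
F(p-1, n-p) law assumes.  The non-parametric scheme: re-run community
detection under seeds 1..n_seeds, match each original cluster to its
best-Jaccard counterpart per seed, retain the top ``keep`` matches, and for
each retained reassigned cluster permute the cell coordinate pairs and refit
to obtain null F statistics.  A Gamma distribution fitted to each gene's
null values gives a smooth upper-tail p-value, adjusted by Benjamini-
Hochberg within the cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import GraphClustering
from .spline import build_design, fit_genes, isolation_mask

logger = logging.getLogger(__name__)

MIN_NULLS = 30


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass
class Reassignment:
    """One matched reassigned cluster: member cell indices, Jaccard, source seed."""

    cells: np.ndarray
    jaccard: float
    seed: int


def build_reassignments(
    clustering: GraphClustering,
    original_labels: np.ndarray,
    n_seeds: int = 1000,
    keep: int = 100,
) -> dict[int, list[Reassignment]]:
    """Top-``keep`` best-Jaccard reassigned clusters per original cluster.

    Community detection is re-run under seeds 1..n_seeds on the cached graph;
    for every seed each original cluster keeps its best match (ties to the
    smaller reassigned label), and across seeds the ``keep`` highest-Jaccard
    matches are retained (ties to the smaller seed).  Matching is independent
    per original cluster: two originals may match the same reassigned set.
    """
    if keep > n_seeds:
        raise ValueError("keep cannot exceed n_seeds")
    original_labels = np.asarray(original_labels)
    originals = {c: set(np.flatnonzero(original_labels == c)) for c in np.unique(original_labels)}
    matches: dict[int, list[Reassignment]] = {c: [] for c in originals}
    for seed in range(1, n_seeds + 1):
        labels = clustering.cluster(seed)
        groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
        group_sets = [set(g) for g in groups]
        for c, cset in originals.items():
            best_j, best_g = -1.0, None
            for g, gset in enumerate(group_sets):
                jac = jaccard(cset, gset)
                if jac > best_j:
                    best_j, best_g = jac, g
            matches[c].append(Reassignment(cells=groups[best_g], jaccard=best_j, seed=seed))
    for c in matches:
        matches[c].sort(key=lambda r: (-r.jaccard, r.seed))
        matches[c] = matches[c][:keep]
    return matches


def null_statistics(
    expression: np.ndarray,
    coords: np.ndarray,
    reassignments: list[Reassignment],
    n_knots: int = 2,
    rng_seed: int = 0,
    min_nulls: int = MIN_NULLS,
) -> np.ndarray:
    """Null F matrix (n_reassignments x genes) from permuted reassigned clusters.

    ``expression`` holds the original cluster's retained genes over *all*
    cells (genes x n_total); each reassigned cluster is isolation-filtered,
    its coordinate pairs are permuted uniformly at random (s1 and s2 move
    together), the design is rebuilt and every gene refitted.  Reassigned
    clusters too small to fit are skipped with a warning; fewer than
    ``min_nulls`` usable reassignments aborts testing for the cluster.
    """
    rng = np.random.default_rng(rng_seed)
    coords = np.asarray(coords, dtype=float)
    nulls = []
    for r in reassignments:
        idx = np.asarray(r.cells)
        idx = idx[isolation_mask(coords[idx])]
        sub = coords[idx]
        perm = rng.permutation(len(idx))
        try:
            design = build_design(sub[perm], n_knots)
        except ValueError as err:
            logger.warning("skipping reassigned cluster (seed %d): %s", r.seed, err)
            continue
        nulls.append(fit_genes(design, expression[:, idx]).f_stat)
    if len(nulls) < min_nulls:
        raise RuntimeError(
            f"only {len(nulls)} usable reassigned clusters (< {min_nulls}); "
            "testing aborted for this cluster"
        )
    return np.asarray(nulls)


def gamma_pvalue(observed: float, nulls: np.ndarray, min_nulls: int = MIN_NULLS):
    """Upper-tail p-value of the observed F under a Gamma fitted to the nulls.

    Maximum likelihood with method-of-moments initialization and the location
    fixed at zero; zero nulls are replaced by the smallest positive null
    x 1e-3.  If the fit fails, falls back to the empirical permutation
    p-value (1 + #{null >= observed}) / (1 + #nulls).

    Returns ``(p, shape, rate)``; shape/rate are NaN on fallback.
    """
    nulls = np.asarray(nulls, dtype=float)
    if len(nulls) < min_nulls:
        raise ValueError(f"need at least {min_nulls} null statistics, got {len(nulls)}")
    positive = nulls[nulls > 0]
    empirical = (1.0 + np.sum(nulls >= observed)) / (1.0 + len(nulls))
    if len(positive) == 0:
        return empirical, np.nan, np.nan
    filled = np.where(nulls > 0, nulls, positive.min() * 1e-3)
    m, v = filled.mean(), filled.var(ddof=1)
    if v <= 0:
        return empirical, np.nan, np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _, scale = scipy.stats.gamma.fit(filled, m * m / v, floc=0, scale=v / m)
        p = float(scipy.stats.gamma.sf(observed, shape, scale=scale))
        if not (np.isfinite(shape) and shape > 0 and np.isfinite(scale) and scale > 0):
            raise ValueError("degenerate Gamma fit")
    except Exception:
        return empirical, np.nan, np.nan
    return p, float(shape), float(1.0 / scale)


def gamma_pvalues(observed: np.ndarray, nulls: np.ndarray, min_nulls: int = MIN_NULLS):
    """Vectorized :func:`gamma_pvalue` over genes (``nulls`` is n_nulls x genes)."""
    out_p = np.empty(len(observed))
    out_shape = np.empty(len(observed))
    out_rate = np.empty(len(observed))
    for i, f in enumerate(observed):
        out_p[i], out_shape[i], out_rate[i] = gamma_pvalue(f, nulls[:, i], min_nulls=min_nulls)
    return out_p, out_shape, out_rate


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with monotonicity enforcement."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def parametric_pvalue_baseline(observed, n: int, p: int) -> np.ndarray:
    """Upper tail of F(p-1, n-p): the parametric per-cluster baseline that
    ignores clustering uncertainty."""
    if n <= p:
        raise ValueError("need n > p")
    return scipy.stats.f.sf(observed, p - 1, n - p)
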