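"""Gene modules, metagenes, marker-gene comparison and set enrichment.

Significant SVGs of a cluster are grouped into modules by k-means on their
standardized fitted surfaces; the module count is chosen at the elbow of the
within-SS / total-SS curve (maximum perpendicular distance to the chord).
A module's metagene is the per-cell mean of its members' standardized fits.
Marker genes come from a per-cluster Wilcoxon rank-sum test, and modules can
be tested against user-supplied gene sets with a hypergeometric
overrepresentation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.cluster import KMeans

from .containers import CellMatrix
from .testing import adjust_bh

logger = logging.getLogger(__name__)


@dataclass
class GeneModule:
    module_id: int
    genes: list[str]
    metagene: np.ndarray


@dataclass
class ModuleSet:
    modules: list[GeneModule]
    chosen_k: int
    wss_curve: np.ndarray  # within-SS / total-SS for k = 1..k_max


def _elbow(curve: np.ndarray) -> int:
    """1-based elbow index: maximum perpendicular distance to the chord
    from the first to the last point of the curve."""
    k = np.arange(1, len(curve) + 1, dtype=float)
    x0, y0, x1, y1 = k[0], curve[0], k[-1], curve[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (k - x0) - dx * (curve - y0)) / norm
    return int(np.argmax(dist)) + 1


def cluster_gene_modules(
    standardized: pd.DataFrame, k_max: int = 15, seed: int = 0, n_init: int = 25
) -> ModuleSet:
    """Partition genes (rows of ``standardized``) into spatial-pattern modules.

    k-means is run for k = 1..k_max (capped at the gene count); the module
    count is the elbow of the within-SS/total-SS curve.  Fewer than 2 genes
    yield a single module.
    """
    genes = list(standardized.index)
    X = standardized.to_numpy(dtype=float)
    if len(genes) < 2:
        meta = X.mean(axis=0) if len(genes) else np.zeros(standardized.shape[1])
        return ModuleSet(
            modules=[GeneModule(0, genes, meta)], chosen_k=1, wss_curve=np.array([1.0])
        )
    k_max = min(k_max, len(genes))
    total_ss = ((X - X.mean(axis=0)) ** 2).sum()
    curve = np.empty(k_max)
    fits = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        fits[k] = km
        curve[k - 1] = km.inertia_ / total_ss if total_ss > 0 else 0.0
    chosen = 1 if total_ss == 0 else _elbow(curve)
    labels = fits[chosen].labels_
    modules = []
    for m in range(chosen):
        members = [g for g, l in zip(genes, labels) if l == m]
        modules.append(GeneModule(m, members, X[labels == m].mean(axis=0)))
    return ModuleSet(modules=modules, chosen_k=chosen, wss_curve=curve)


def metagene(module: GeneModule, standardized: pd.DataFrame) -> np.ndarray:
    """Per-cell unweighted mean of the module members' standardized fits."""
    if not module.genes:
        raise ValueError("empty module")
    return standardized.loc[module.genes].to_numpy(dtype=float).mean(axis=0)


@dataclass
class MarkerSet:
    per_cluster: dict[int, pd.DataFrame]  # gene, p, lfc ordered by ascending p
    union: set[str]


def find_markers(
    cells: CellMatrix,
    labels: np.ndarray | None = None,
    normalized=None,
    max_cells_per_cluster: int = 5000,
    top_n: int = 50,
    seed: int = 0,
) -> MarkerSet:
    """Per-cluster differential genes: Wilcoxon rank-sum, cluster vs rest.

    Each cluster is first downsampled (seeded) to ``max_cells_per_cluster``
    cells; per cluster the ``top_n`` smallest-p genes are reported (ties
    broken by descending absolute log fold change) and their union returned.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    from .preprocessing import lognormalize

    labels = cells.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("cluster labels required")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    if normalized is None:
        normalized = lognormalize(cells)
    X = np.asarray(normalized.todense() if sp.issparse(normalized) else normalized, float)

    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > max_cells_per_cluster:
            idx = np.sort(rng.choice(idx, size=max_cells_per_cluster, replace=False))
        keep.append(idx)
    keep = np.concatenate(keep)
    X = X[:, keep]
    labels = labels[keep]

    per_cluster: dict[int, pd.DataFrame] = {}
    union: set[str] = set()
    genes = np.asarray(cells.genes)
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() < 3:
            logger.warning("cluster %s skipped in marker search: < 3 cells", c)
            continue
        inside, outside = X[:, mask], X[:, ~mask]
        res = scipy.stats.mannwhitneyu(
            inside, outside, axis=1, alternative="two-sided", method="asymptotic"
        )
        lfc = inside.mean(axis=1) - outside.mean(axis=1)
        df = pd.DataFrame({"gene": genes, "p": res.pvalue, "lfc": lfc})
        df = df.sort_values(
            ["p", "lfc"], ascending=[True, False], key=lambda s: s.abs() if s.name == "lfc" else s
        ).head(top_n)
        per_cluster[int(c)] = df.reset_index(drop=True)
        union.update(df["gene"])
    return MarkerSet(per_cluster=per_cluster, union=union)


def svg_marker_overlap(svg_ranking: list[str], markers: MarkerSet, top_k: int) -> float:
    """Fraction of the top-k ranked SVGs absent from the marker union."""
    if top_k > len(svg_ranking):
        logger.warning("top_k=%d exceeds ranking length %d; clamped", top_k, len(svg_ranking))
        top_k = len(svg_ranking)
    top = svg_ranking[:top_k]
    return sum(g not in markers.union for g in top) / top_k


def enrich_gene_sets(
    module_genes: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each gene set in a module.

    One-sided tail p per set, BH-adjusted; sets at FDR <= ``fdr_cutoff`` are
    returned ordered by decreasing fold change (observed / expected overlap).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    module = set(module_genes) & universe_set
    rows = []
    N, n = len(universe_set), len(module)
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        K = len(in_universe)
        if K == 0:
            continue
        k = len(module & in_universe)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        expected = K * n / N
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "expected": expected,
                "fold_change": k / expected if expected > 0 else np.nan,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "expected", "fold_change", "p", "fdr"])
    df = pd.DataFrame(rows)
    df["fdr"] = adjust_bh(df["p"].to_numpy())
    df = df[df["fdr"] <= fdr_cutoff]
    return df.sort_values("fold_change", ascending=False).reset_index(drop=True)
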