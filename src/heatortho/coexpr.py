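"""Weighted co-expression modules from first principles.

The module detector follows the classic weighted-network recipe: a
soft-thresholded Pearson correlation network (unsigned |r|^beta by
default, signed ((1+r)/2)^beta optionally), the scale-free topology
criterion to pick beta, topological-overlap similarity
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), average-linkage
hierarchical clustering of 1 - TOM with a static cut, first-principal-
component eigengenes, and greedy merging of modules with highly
correlated eigengenes.  A deterministic static cut (by default at the
largest gap between consecutive merge heights) replaces dynamic tree
cutting; downstream analyses only require that coherent modules exist,
not any particular cut algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ValidationError
from .quantify import ExpressionMatrix

logger = logging.getLogger("heatortho")

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene_id -> module label ("M1", ..., "unassigned")
    eigengenes: pd.DataFrame = field(default=None)  # modules x samples, unit rows
    chosen_power: float = None
    scale_free_r2: float = None

    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]


def _corr(expr_values: np.ndarray) -> np.ndarray:
    sd = expr_values.std(axis=1)
    if np.any(sd == 0):
        idx = int(np.where(sd == 0)[0][0])
        raise ValidationError(f"zero variance gene at row {idx}")
    return np.corrcoef(expr_values)


def adjacency(expr: ExpressionMatrix, power: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded correlation adjacency with zero diagonal."""
    vals = expr.values.to_numpy()
    if vals.shape[1] < 3:
        raise ValidationError("need at least 3 samples for co-expression")
    cor = _corr(vals)
    if signed:
        a = ((1.0 + cor) / 2.0) ** power
    else:
        a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression over connectivity bins."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 10:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / k.size)
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_soft_power(
    expr: ExpressionMatrix,
    power_grid=(1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16),
    r2_target: float = 0.8,
    signed: bool = False,
):
    """Smallest power whose scale-free fit reaches the target R^2."""
    grid = tuple(power_grid)
    if not grid:
        raise ValidationError("empty power grid")
    if expr.values.shape[0] < 20:
        raise ValidationError("need >= 20 genes for a stable scale-free fit")
    fits = {}
    for power in grid:
        a = adjacency(expr, power, signed=signed)
        fits[power] = scale_free_fit(a.sum(axis=1))
        if fits[power] >= r2_target:
            return power, fits[power]
    # no power reaches the target (common for small or strongly modular
    # data, which is not scale-free); fall back to the conventional
    # default soft power rather than chasing the best of a bad fit
    default = 12.0 if signed else 6.0
    fallback = min(grid, key=lambda p: abs(p - default))
    logger.warning(
        "no power in grid reached scale-free R^2 %.2f; falling back to the "
        "conventional power %s (R^2 %.3f)", r2_target, fallback, fits[fallback],
    )
    return fallback, fits[fallback]


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric zero-diagonal adjacency."""
    adj = np.asarray(adj, dtype=float)
    if adj.shape[0] != adj.shape[1] or not np.allclose(adj, adj.T, atol=1e-10):
        raise ValidationError("adjacency must be square and symmetric")
    l = adj @ adj  # shared-neighbour weight (diagonal never read)
    k = adj.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (l + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def cluster_modules(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    cut_height: float | None = None,
    cut_height_fraction: float | None = None,
    gene_ids=None,
) -> pd.Series:
    """Average-linkage clustering of a dissimilarity with a static cut.

    The cut height is, in order of precedence: ``cut_height`` if given;
    ``cut_height_fraction`` times the tree height; otherwise the midpoint
    of the largest gap between consecutive merge heights.  The gap rule is
    deterministic and lands between the within-cluster and between-cluster
    merges whenever the tree separates cleanly, where any fixed fraction
    of the (data-dependent) tree height can straddle them.

    Clusters smaller than ``min_module_size`` become "unassigned"; the rest
    are labelled M1, M2, ... in decreasing size (ties by first gene index,
    keeping labels deterministic).
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    link = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        heights = link[:, 2]
        if cut_height_fraction is not None:
            cut_height = cut_height_fraction * heights[-1] if len(link) else 0.0
        elif len(heights) >= 2:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            cut_height = 0.5 * (heights[i] + heights[i + 1])
        else:
            cut_height = heights[-1] if len(heights) else 0.0
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    return pd.Series(labels, index=gene_ids, name="module")


def _relabel_by_size(raw: np.ndarray, min_module_size: int) -> list[str]:
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first.setdefault(c, i)
    kept = [c for c in sizes if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], first[c]))
    name = {c: f"M{i + 1}" for i, c in enumerate(kept)}
    return [name.get(c, UNASSIGNED) for c in raw]


def module_eigengene(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module across samples (unit norm).

    Genes are standardized first; the eigengene sign is anchored so the
    average gene-eigengene correlation is non-negative.
    """
    vals = expr.values
    rows = {}
    for module in sorted(set(labels) - {UNASSIGNED}, key=_module_key):
        genes = labels.index[labels == module]
        if len(genes) < 2:
            raise ValidationError(f"module {module} has fewer than 2 genes")
        x = vals.loc[genes].to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValidationError(f"zero variance gene in module {module}")
        z = (x - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        if np.mean(z @ eig) < 0:
            eig = -eig
        rows[module] = eig / np.linalg.norm(eig)
    return pd.DataFrame(rows, index=vals.columns).T


def _module_key(label: str):
    return (0, int(label[1:])) if label[1:].isdigit() else (1, label)


def merge_modules(
    expr: ExpressionMatrix, labels: pd.Series, merge_corr_threshold: float = 0.85
) -> pd.Series:
    """Greedily merge modules whose eigengenes correlate above the threshold.

    The most correlated pair merges first (ties broken by smaller label),
    eigengenes are recomputed, and the process repeats to a fixed point.
    """
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED}, key=_module_key)
        if len(modules) < 2:
            return labels
        eig = module_eigengene(expr, labels)
        cor = np.corrcoef(eig.loc[modules].to_numpy())
        best, best_val = None, -np.inf
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                if cor[i, j] >= merge_corr_threshold and cor[i, j] > best_val:
                    best, best_val = (i, j), cor[i, j]
        if best is None:
            return labels
        i, j = best
        labels[labels == modules[j]] = modules[i]


def detect_modules(
    expr: ExpressionMatrix,
    power_grid=(1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16),
    r2_target: float = 0.8,
    signed: bool = False,
    min_module_size: int = 30,
    cut_height: float | None = None,
    cut_height_fraction: float | None = None,
    merge_corr_threshold: float = 0.85,
    max_genes: int | None = None,
) -> ModuleAssignment:
    """Full module detection on an rlog expression matrix.

    Zero-variance genes are dropped (with a logged count); if ``max_genes``
    is set, only the most variable genes enter the network and the rest are
    reported unassigned.
    """
    vals = expr.values
    sd = vals.std(axis=1)
    dropped = sd[sd == 0].index
    if len(dropped):
        logger.info("dropping %d zero-variance genes", len(dropped))
    kept = vals.loc[sd > 0]
    if max_genes is not None and len(kept) > max_genes:
        order = kept.var(axis=1).sort_values(ascending=False, kind="mergesort")
        kept = kept.loc[order.index[:max_genes]].sort_index()
    sub = ExpressionMatrix(kept, expr.kind)
    power, r2 = pick_soft_power(sub, power_grid, r2_target, signed=signed)
    adj = adjacency(sub, power, signed=signed)
    tom = tom_similarity(adj)
    labels = cluster_modules(
        1.0 - tom,
        min_module_size=min_module_size,
        cut_height=cut_height,
        cut_height_fraction=cut_height_fraction,
        gene_ids=list(kept.index),
    )
    labels = merge_modules(sub, labels, merge_corr_threshold)
    # re-rank surviving module labels by size after merging
    full = pd.Series(UNASSIGNED, index=vals.index, name="module")
    assigned = labels[labels != UNASSIGNED]
    eig = None
    if len(assigned):
        raw = pd.factorize(assigned)[0]
        renamed = pd.Series(_relabel_by_size(raw + 1, 1), index=assigned.index)
        full.loc[renamed.index] = renamed
        eig = module_eigengene(sub, full.loc[kept.index])
    return ModuleAssignment(full, eig, power, r2)
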