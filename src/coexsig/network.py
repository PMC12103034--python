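"""Weighted co-expression network construction.

Pipeline: pick (or override) a soft-threshold power by the scale-free fit
criterion, raise absolute Pearson correlations to that power (unsigned
adjacency), convert to topological overlap, cluster genes by average
linkage on 1 - TOM, and extract modules with a dynamic tree cut.

The tree cut used here makes the usual hybrid contract explicit: a static
cut just below the dendrogram top yields candidate clusters, which are
then recursively split wherever the merge gap between a node and its
children is large enough; ``deep_split`` (0..4) maps to a decreasing
minimum-gap ladder, so a higher value can only produce more (smaller)
modules.  Genes left unassigned can be pulled into a module by mean-TOM
proximity (``method="hybrid"``); ``method="tree"`` skips that stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

# deep_split 0..4 -> minimum merge gap (fraction of the dendrogram height
# range) required to split a cluster; derived from the published
# split-sensitivity ladder (core scatter 0.64..0.95, gap = (1 - scatter) * 3/4)
_MIN_GAP = (0.270, 0.2025, 0.135, 0.0675, 0.0375)

GREY = 0


@dataclass
class NetworkModel:
    """A fitted co-expression network: power, TOM, dendrogram, labels."""

    power: int
    tom: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray               # per-gene module id, 0 = grey
    gene_ids: pd.Index
    min_module_size: int = 50
    deep_split: int = 2
    merge_cut_height: float | None = None

    def module_sizes(self) -> pd.Series:
        lab = pd.Series(self.labels, index=self.gene_ids)
        return lab[lab != GREY].value_counts().sort_index()

    def module_genes(self, module: int) -> list:
        return list(self.gene_ids[self.labels == module])

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_id": self.labels,
                "module_label": [f"M{m:02d}" if m != GREY else "grey" for m in self.labels],
            },
            index=self.gene_ids,
        )


# ---------------------------------------------------------------------------
# soft threshold


def _check_constant_rows(values: np.ndarray, gene_ids) -> None:
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(np.asarray(gene_ids)[sd == 0])
        raise ValueError(f"constant expression for genes: {bad[:10]}")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the binned log10(freq) ~ log10(k) fit.

    Connectivities are binned into equal-width bins; empty bins are
    dropped.  The R^2 is negated when the slope is positive (a scale-free
    topology has a falling tail).
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-np.sign(slope) * r2 if slope != 0 else 0.0), slope


def pick_soft_threshold(
    values: pd.DataFrame | np.ndarray,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.80,
    n_bins: int = 10,
    min_mean_k: float = 1.0,
) -> tuple[pd.DataFrame, int | None]:
    """Scale-free-fit table over candidate powers and the chosen power.

    Chosen = smallest power whose signed R^2 reaches ``r2_target`` while
    mean connectivity stays at or above ``min_mean_k``; None when no
    candidate qualifies (e.g. pure noise data).  The connectivity floor
    matters: at very high powers the connectivity of *any* dataset is
    dominated by each gene's single largest correlation, whose heavy tail
    mimics a scale-free fit even for noise, but the resulting network is
    degenerate (mean k near zero).  An explicit override power can always
    be passed straight to :func:`build_adjacency`.
    """
    arr = np.asarray(values, float)
    if arr.shape[1] < 4:
        raise ValueError("soft-threshold selection needs at least 4 samples")
    if arr.shape[0] < 20:
        raise ValueError("soft-threshold selection needs at least 20 genes")
    gene_ids = values.index if isinstance(values, pd.DataFrame) else np.arange(arr.shape[0])
    _check_constant_rows(arr, gene_ids)
    abs_cor = np.abs(np.corrcoef(arr))
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    chosen = None
    for beta in powers:
        k = (abs_cor ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": int(beta),
                "sft_r2": r2,
                "slope": slope,
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
            }
        )
        if chosen is None and r2 >= r2_target and k.mean() >= min_mean_k:
            chosen = int(beta)
    return pd.DataFrame(rows).set_index("power"), chosen


# ---------------------------------------------------------------------------
# adjacency and TOM


def build_adjacency(values: pd.DataFrame | np.ndarray, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^power with unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    arr = np.asarray(values, float)
    gene_ids = values.index if isinstance(values, pd.DataFrame) else np.arange(arr.shape[0])
    _check_constant_rows(arr, gene_ids)
    adj = np.abs(np.corrcoef(arr)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor-weighted similarity in [0, 1].

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the connectivity of i.
    """
    A = np.asarray(adjacency, float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    # (off @ off)_ij sums a_iu a_uj over u != i and u != j automatically
    L = off @ off
    denom = np.minimum.outer(k, k) + 1.0 - off
    tom = (L + off) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# clustering and dynamic cut


def _subtree_leaves(node) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def _cut_static(root, threshold: float) -> list:
    """Maximal subtrees whose merge height is <= threshold."""
    clusters = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.dist <= threshold or node.is_leaf():
            clusters.append(node)
        else:
            stack.extend([node.left, node.right])
    return clusters


def _refine(node, min_size: int, min_gap: float, out: list) -> None:
    """Recursively split a cluster wherever the merge gap is large enough."""
    if not node.is_leaf():
        child_top = max(node.left.dist, node.right.dist)
        gap = node.dist - child_top
        if (
            gap >= min_gap
            and node.left.count >= min_size
            and node.right.count >= min_size
        ):
            _refine(node.left, min_size, min_gap, out)
            _refine(node.right, min_size, min_gap, out)
            return
    out.append(node)


def cluster_and_cut(
    tom: np.ndarray,
    min_module_size: int = 50,
    deep_split: int = 2,
    method: str = "hybrid",
    cut_fraction: float = 0.99,
    expr: "pd.DataFrame | np.ndarray | None" = None,
    kme_threshold: float = 0.4,
    refine_rounds: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering on 1 - TOM plus dynamic module extraction.

    Returns ``(linkage, labels)`` with labels 0 (grey) or 1..K ordered by
    decreasing module size (ties broken by smallest member index).

    ``method="hybrid"`` follows the dendrogram cut with a membership
    refinement stage: when ``expr`` is given, every gene is iteratively
    reassigned to the module whose eigengene it correlates with most
    (grey when that kME falls below ``kme_threshold``); without ``expr``
    unassigned genes are pulled in by mean-TOM proximity only.  The
    default kME floor of 0.4 sits ~2.5 null standard deviations above
    chance correlation at the cohort sizes the package targets, so genes
    correlated with a module only by sampling luck stay grey.
    ``method="tree"`` is the plain dendrogram cut.
    """
    n = tom.shape[0]
    if min_module_size > n:
        raise ValueError("min_module_size exceeds the number of genes")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if method not in ("hybrid", "tree"):
        raise ValueError("method must be 'hybrid' or 'tree'")
    diss = 1.0 - np.asarray(tom, float)
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    root = hierarchy.to_tree(Z)
    hmax = float(Z[:, 2].max()) if len(Z) else 0.0
    hrange = hmax - float(Z[:, 2].min()) if len(Z) else 0.0

    clusters = _cut_static(root, cut_fraction * hmax)
    if hrange > 0:
        min_gap = _MIN_GAP[deep_split] * hrange
        refined: list = []
        for node in clusters:
            if node.count >= min_module_size:
                _refine(node, min_module_size, min_gap, refined)
            else:
                refined.append(node)
        clusters = refined

    labels = np.zeros(n, dtype=int)
    modules = [sorted(_subtree_leaves(c)) for c in clusters if c.count >= min_module_size]
    modules.sort(key=lambda m: (-len(m), m[0]))
    for k, members in enumerate(modules, start=1):
        labels[members] = k

    if method == "hybrid" and modules:
        if expr is not None:
            labels = _refine_by_kme(expr, labels, kme_threshold, refine_rounds)
        else:
            off = np.asarray(tom, float).copy()
            np.fill_diagonal(off, 0.0)
            intra_mean = {}
            for k, members in enumerate(modules, start=1):
                sub = off[np.ix_(members, members)]
                m = len(members)
                intra_mean[k] = sub.sum() / (m * (m - 1))
            grey_idx = np.flatnonzero(labels == GREY)
            for g in grey_idx:
                best_k, best_sim = GREY, -1.0
                for k, members in enumerate(modules, start=1):
                    sim = off[g, members].mean()
                    if sim > best_sim:
                        best_k, best_sim = k, sim
                if best_k != GREY and best_sim >= 0.5 * intra_mean[best_k]:
                    labels[g] = best_k
        labels = _relabel_by_size(labels)

    return Z, labels


def _refine_by_kme(expr, labels: np.ndarray, threshold: float, rounds: int) -> np.ndarray:
    """Iteratively reassign every gene to its best-correlated module eigengene.

    A gene joins the module maximizing kME = cor(gene, eigengene) when that
    correlation reaches `threshold`, and is grey otherwise; eigengenes are
    recomputed each round.  Module count is taken from the dendrogram cut
    and modules that lose too many members are left as they stand.
    """
    from .modules import compute_eigengenes   # local import: avoids cycle

    arr = expr if isinstance(expr, pd.DataFrame) else pd.DataFrame(np.asarray(expr, float))
    X = arr.to_numpy(float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd
    labels = labels.copy()
    for _ in range(rounds):
        mods = [k for k in np.unique(labels) if k != GREY]
        if not mods or any((labels == k).sum() < 2 for k in mods):
            break
        me = compute_eigengenes(arr, labels).values
        kme = np.empty((X.shape[0], len(mods)))
        for j, k in enumerate(mods):
            v = me[k].to_numpy()
            v = (v - v.mean()) / np.linalg.norm(v - v.mean())
            kme[:, j] = Xs @ v / np.sqrt(X.shape[1] - 1)
        best = np.argmax(kme, axis=1)
        best_val = kme[np.arange(len(best)), best]
        new = np.where(best_val >= threshold, np.asarray(mods)[best], GREY)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..K by decreasing size, ties by smallest member index."""
    out = np.zeros_like(labels)
    modules = []
    for k in np.unique(labels):
        if k == GREY:
            continue
        members = np.flatnonzero(labels == k)
        modules.append((-len(members), members[0], members))
    modules.sort(key=lambda t: (t[0], t[1]))
    for new_k, (_, _, members) in enumerate(modules, start=1):
        out[members] = new_k
    return out


def merge_close_modules(
    values: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    cut_height: float = 0.1,
) -> np.ndarray:
    """Merge module pairs whose eigengene dissimilarity 1 - cor is below cut.

    Eigengenes are recomputed after each merge; the final labels are
    renumbered by size.  A no-op when nothing is close enough.
    """
    from .modules import compute_eigengenes   # local import: avoids cycle

    labels = np.asarray(labels).copy()
    if cut_height <= 0:
        return labels
    arr = values if isinstance(values, pd.DataFrame) else pd.DataFrame(np.asarray(values, float))
    while True:
        mods = [k for k in np.unique(labels) if k != GREY]
        if len(mods) < 2:
            break
        eig = compute_eigengenes(arr, labels)
        me = eig.values
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                diss = 1.0 - np.corrcoef(me[a], me[b])[0, 1]
                if diss < cut_height and (best is None or diss < best[0]):
                    best = (diss, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
    return _relabel_by_size(labels)


# ---------------------------------------------------------------------------
# edge export


def export_top_edges(
    tom: np.ndarray,
    gene_ids: Sequence,
    labels: np.ndarray,
    module: int,
    n_edges: int = 600,
) -> pd.DataFrame:
    """Strongest intra-module TOM edges plus within-export node degrees.

    Ties in weight break lexicographically on the (source, target) gene-id
    pair so exports are reproducible.
    """
    members = np.flatnonzero(np.asarray(labels) == module)
    if len(members) < 2:
        raise ValueError(f"module {module} has fewer than 2 genes")
    ids = np.asarray(gene_ids)
    pairs = []
    for ai in range(len(members)):
        for bi in range(ai + 1, len(members)):
            i, j = members[ai], members[bi]
            a, b = sorted((str(ids[i]), str(ids[j])))
            pairs.append((-float(tom[i, j]), a, b))
    pairs.sort()
    pairs = pairs[: int(n_edges)]
    edges = pd.DataFrame(
        [(a, b, -negw) for negw, a, b in pairs],
        columns=["source", "target", "weight"],
    )
    degree = pd.concat([edges["source"], edges["target"]]).value_counts()
    edges["source_degree"] = edges["source"].map(degree)
    edges["target_degree"] = edges["target"].map(degree)
    return edges
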