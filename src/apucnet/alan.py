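"""Second-order gene-association networks (ALAN-style).

First order: the Spearman correlation of every gene pair across samples.
Second order: for genes i and j, the Pearson correlation of their first-order
correlation *profiles* (row i and row j of the first-order matrix) after
removing the self-columns i and j from both rows. Two genes are strongly
associated at second order when they relate to the rest of the transcriptome
in the same way — "gene behaviour" — even if their direct correlation is
modest. Rank-based first order makes the result invariant to any monotone
per-gene transform of the expression unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import AlanMatrix, ExpressionMatrix

__all__ = [
    "first_order_correlation",
    "alan_matrix",
    "alan_profile",
    "cluster_hierarchical",
    "embed_profiles",
    "coalescence_score",
    "ClusterResult",
]


def _constant_genes(values: pd.DataFrame) -> list[str]:
    arr = values.to_numpy()
    const = np.all(arr == arr[:, :1], axis=1)
    return list(values.index[const])


def first_order_correlation(m: ExpressionMatrix, method: str = "spearman") -> pd.DataFrame:
    """Gene × gene correlation matrix across samples.

    Constant genes yield NaN rows/columns (undefined correlation); the
    diagonal is set to 1 regardless.
    """
    n_genes, n_samples = m.shape
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    if n_genes < 2:
        raise ValueError(f"need >= 2 genes, got {n_genes}")
    arr = m.values.to_numpy(dtype=float)
    if method == "spearman":
        arr = np.apply_along_axis(rankdata, 1, arr)  # average ranks for ties
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(arr)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return pd.DataFrame(c, index=m.gene_ids, columns=m.gene_ids)


def alan_matrix(m: ExpressionMatrix, first_order: str = "spearman") -> AlanMatrix:
    """Second-order association matrix for all gene pairs.

    For each pair (i, j) the entry is the Pearson correlation of first-order
    profile rows C_i and C_j with columns i and j removed from both; the
    diagonal is defined as exactly 1. Computed in closed form from row sums,
    squared sums and the Gram matrix of C, so no per-pair loop is needed.
    """
    n_genes, n_samples = m.shape
    if n_genes < 4:
        raise ValueError(f"need >= 4 genes, got {n_genes}")
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    const = _constant_genes(m.values)
    if const:
        raise ValueError(
            f"constant genes (undefined correlation): {const}; "
            "apply filter_zero_genes or a variance filter first"
        )
    c = first_order_correlation(m, method=first_order).to_numpy()

    n2 = n_genes - 2
    s = c.sum(axis=1)
    q = (c**2).sum(axis=1)
    gram = c @ c.T
    # sums over the kept columns (all k except i and j), using C_ii = 1
    sx = s[:, None] - 1.0 - c
    sy = s[None, :] - 1.0 - c
    sxx = q[:, None] - 1.0 - c**2
    syy = q[None, :] - 1.0 - c**2
    sxy = gram - 2.0 * c
    cov = sxy - sx * sy / n2
    vx = sxx - sx**2 / n2
    vy = syy - sy**2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = cov / np.sqrt(vx * vy)
    np.fill_diagonal(a, 1.0)
    if not np.isfinite(a).all():
        bad = list(pd.Index(m.gene_ids)[~np.isfinite(a).all(axis=1)])
        raise ValueError(f"degenerate (constant) correlation profiles for genes: {bad}")
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return AlanMatrix(
        values=pd.DataFrame(a, index=m.gene_ids, columns=m.gene_ids),
        method_meta={"first_order": first_order, "second_order": "pearson"},
    )


def alan_profile(a: AlanMatrix | pd.DataFrame, gene: str) -> pd.Series:
    """A gene's association vector over all other genes (self entry dropped)."""
    values = a.values if isinstance(a, AlanMatrix) else a
    if gene not in values.index:
        raise KeyError(f"unknown gene {gene!r}")
    return values.loc[gene].drop(gene)


class ClusterResult:
    """Hierarchical clustering result: linkage, leaf order, and cut-at-k labels."""

    def __init__(self, linkage: np.ndarray, ids: list[str]):
        self.linkage = linkage
        self.ids = list(ids)
        self.leaf_order = (
            [self.ids[i] for i in sch.leaves_list(linkage)] if len(ids) > 1 else list(ids)
        )

    def cut(self, k: int) -> pd.Series:
        if len(self.ids) == 1:
            return pd.Series([1], index=self.ids)
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.ids)


def cluster_hierarchical(d: pd.DataFrame, on: str = "genes") -> ClusterResult:
    """Average-linkage hierarchical clustering.

    ``genes`` mode takes a symmetric similarity matrix in [−1, 1] (e.g. an
    association matrix) and clusters on distance 1 − similarity. ``samples``
    mode takes a z-scored expression matrix (genes × samples) and clusters its
    columns on Euclidean distance.
    """
    if on == "genes":
        arr = d.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("genes mode requires a symmetric square similarity matrix")
        ids = list(d.index)
        if len(ids) == 1:
            return ClusterResult(np.empty((0, 4)), ids)
        dist = 1.0 - arr
        np.fill_diagonal(dist, 0.0)
        z = sch.linkage(squareform(dist, checks=False), method="average")
        return ClusterResult(z, ids)
    if on == "samples":
        ids = list(d.columns)
        if len(ids) == 1:
            return ClusterResult(np.empty((0, 4)), ids)
        z = sch.linkage(pdist(d.to_numpy(dtype=float).T, metric="euclidean"), method="average")
        return ClusterResult(z, ids)
    raise ValueError(f"unknown mode {on!r}")


def embed_profiles(a: AlanMatrix, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """2-D neighbourhood embedding (UMAP) of association profiles.

    Each gene's feature vector is its row of the association matrix; genes
    with similar transcriptome-wide behaviour land close together.
    Deterministic for a fixed seed.
    """
    import umap  # deferred: heavy import

    n = len(a.gene_ids)
    if n < 10:
        raise ValueError(f"need >= 10 genes to embed, got {n}")
    reducer = umap.UMAP(
        n_components=2, random_state=seed, n_neighbors=min(n_neighbors, n - 1)
    )
    coords = reducer.fit_transform(a.values.to_numpy())
    return pd.DataFrame(coords, index=a.gene_ids, columns=["x", "y"])


def coalescence_score(a: AlanMatrix, gene_set: list[str]) -> float:
    """Mean pairwise (off-diagonal) association among a gene set's members.

    Quantifies coalescent behaviour: how strongly the set's genes track each
    other's transcriptome-wide profiles in a given cohort. 1 means identical
    behaviour; 0 is the expectation for unrelated genes.
    """
    present = [g for g in gene_set if g in a.values.index]
    if len(present) < 2:
        raise ValueError(f"need >= 2 set genes present in the matrix, found {present}")
    sub = a.values.loc[present, present].to_numpy()
    off = sub[~np.eye(len(present), dtype=bool)]
    return float(off.mean())
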