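"""Correlation-distance hierarchical clustering of expression profiles.

Profiles (typically subset-mean profiles, so dendrogram leaves are subsets)
are compared with the correlation distance d = 1 - Pearson r over genes and
merged agglomeratively (average linkage by default).  Leaves are
canonicalized to lexicographic order before linkage so the dendrogram is
invariant to the input column order, with ties resolved deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["Dendrogram", "correlation_distance", "hcluster"]


def correlation_distance(m: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between profiles (columns); in [0, 2]."""
    if m.n_samples < 2:
        raise ValueError("need >= 2 profiles")
    if m.n_genes < 2:
        raise ValueError("need >= 2 genes")
    X = m.values.to_numpy().T  # profiles x genes
    sd = X.std(axis=1)
    zero_var = [c for c, s in zip(m.sample_ids, sd) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance profile(s): {zero_var}")
    r = np.corrcoef(X)
    d = 1.0 - r
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry despite float rounding
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


@dataclass
class Dendrogram:
    """Binary merge tree over leaf profiles.

    ``leaves`` is the canonical (lexicographic) leaf order and ``linkage``
    the scipy linkage matrix over that order; merge heights are nonnegative
    and, for average/complete linkage on a metric-like input, nondecreasing
    along any root path.
    """

    leaves: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node, in merge order."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {i: frozenset([self.leaves[i]]) for i in range(n)}
        out: list[frozenset[str]] = []
        for k, (i, j, _, _) in enumerate(self.linkage[:, :4].tolist()):
            merged = members[int(i)] | members[int(j)]
            members[n + k] = merged
            out.append(merged)
        return out

    def are_siblings(self, a: str, b: str) -> bool:
        """True if {a, b} is exactly one of the merge clades."""
        return frozenset([a, b]) in self.clades()

    def smallest_clade_containing(self, leaves: set[str]) -> frozenset[str]:
        for clade in self.clades():
            if leaves <= clade:
                return clade
        return frozenset(self.leaves)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def hcluster(d: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a square distance matrix.

    ``linkage`` is ``average`` or ``complete``.  Input must be symmetric
    with a zero diagonal; leaves are sorted lexicographically first so the
    result does not depend on input order.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    order = sorted(range(len(d.index)), key=lambda i: d.index[i])
    labels = tuple(d.index[i] for i in order)
    arr = arr[np.ix_(order, order)]
    np.fill_diagonal(arr, 0.0)
    Z = hierarchy.linkage(squareform(arr, checks=False), method=linkage)
    return Dendrogram(leaves=labels, linkage=Z)
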