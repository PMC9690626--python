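"""Similarity, UPGMA dendrograms, PCA and heatmap preparation.

Accession relationships in dominant-marker surveys are summarized by a
binary-profile similarity coefficient (Jaccard by default), an average-
linkage (UPGMA) dendrogram exported as Newick, a principal component
analysis of the attribute matrix, and a scaled/ordered matrix feeding a
clustered heatmap.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .band_matrix import BandMatrix

__all__ = [
    "SimilarityMetric",
    "DistanceMatrix",
    "TreeNode",
    "UPGMATree",
    "PCAResult",
    "similarity",
    "upgma",
    "to_newick",
    "pca",
    "heatmap_prepare",
    "HeatmapLayout",
]


class SimilarityMetric(str, enum.Enum):
    JACCARD = "jaccard"
    DICE = "dice"
    SIMPLE_MATCHING = "simple_matching"


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = np.clip(self.values, 0.0, None)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=[str(c) for c in df.index], values=df.to_numpy(float))

    @classmethod
    def euclidean(cls, data: pd.DataFrame) -> "DistanceMatrix":
        return cls(
            labels=[str(i) for i in data.index],
            values=squareform(pdist(data.to_numpy(float))),
        )


@dataclass
class TreeNode:
    """Node of a rooted ultrametric merge tree.

    Leaves carry a ``label`` at height 0; internal nodes carry their merge
    ``height`` (half the between-cluster average distance) and optionally
    a bootstrap ``support`` percentage.
    """

    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [leaf.label or "" for leaf in self.leaves()]


@dataclass
class UPGMATree:
    """Ultrametric UPGMA tree with deterministic child ordering."""

    root: TreeNode
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = self.root.leaf_labels()

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set bipartitions induced by internal edges (rotation-free)."""
        full = frozenset(self.leaf_labels())
        parts = set()
        for node in self.internal_nodes():
            side = frozenset(node.leaf_labels())
            if 1 < len(side) < len(full):
                parts.add(min(side, full - side, key=sorted))
        return parts

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (twice the lowest common height)."""
        labels = sorted(self.leaf_labels())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label or ""]
            sides = [walk(c) for c in node.children]
            for i, left in enumerate(sides):
                for right in sides[i + 1 :]:
                    for a in left:
                        for b in right:
                            values[idx[a], idx[b]] = values[idx[b], idx[a]] = (
                                2.0 * node.height
                            )
            return [x for side in sides for x in side]

        walk(self.root)
        return DistanceMatrix(labels=labels, values=values)


def _profiles(source: BandMatrix | Sequence[BandMatrix]) -> tuple[list[str], np.ndarray]:
    if isinstance(source, BandMatrix):
        return list(source.accession_ids), source.presence
    mats = list(source)
    if not mats:
        raise ValueError("no band matrices given")
    ids = mats[0].accession_ids
    for m in mats[1:]:
        if m.accession_ids != ids:
            raise ValueError("band matrices scored on different accessions")
    return list(ids), np.hstack([m.presence for m in mats])


def similarity(
    source: BandMatrix | Sequence[BandMatrix],
    metric: SimilarityMetric | str = SimilarityMetric.JACCARD,
) -> DistanceMatrix:
    """Pairwise distance (1 - similarity) between binary accession profiles.

    With band counts ``a`` (shared), ``b``/``c`` (private to either) and
    ``d`` (jointly absent): Jaccard ``a/(a+b+c)``, Dice ``2a/(2a+b+c)``,
    simple matching ``(a+d)/(a+b+c+d)``.  A pair with no bands at all is
    undefined under Jaccard/Dice and raises.
    """
    metric = SimilarityMetric(metric)
    labels, x = _profiles(source)
    n = len(labels)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = int(np.sum((x[i] == 1) & (x[j] == 1)))
            b = int(np.sum((x[i] == 1) & (x[j] == 0)))
            c = int(np.sum((x[i] == 0) & (x[j] == 1)))
            d = int(np.sum((x[i] == 0) & (x[j] == 0)))
            if metric is SimilarityMetric.SIMPLE_MATCHING:
                s = (a + d) / (a + b + c + d)
            else:
                if a + b + c == 0:
                    raise ValueError(
                        f"similarity undefined for bandless pair "
                        f"({labels[i]!r}, {labels[j]!r}) under {metric.value}"
                    )
                s = a / (a + b + c) if metric is SimilarityMetric.JACCARD else (
                    2 * a / (2 * a + b + c)
                )
            sim[i, j] = sim[j, i] = s
    return DistanceMatrix(labels=labels, values=1.0 - sim)


def upgma(d: DistanceMatrix) -> UPGMATree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Between-cluster distances are cluster-size-weighted averages (the
    textbook UPGMA update); node heights are half the merge distance, so
    the tree is ultrametric.  Ties are broken by the lexicographically
    smallest pair of cluster keys (a cluster's key is its smallest leaf
    label), which makes output deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two labels")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(d.labels)
    }
    keys = {i: d.labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], *sorted((keys[kv[0][0]], keys[kv[0][1]]))),
        )
        (i, j), dij = best
        left, right = sorted((i, j), key=lambda k: keys[k])
        node = TreeNode(
            height=dij / 2.0, children=(clusters[left], clusters[right])
        )
        size_new = sizes[i] + sizes[j]
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[k] = (sizes[i] * dik + sizes[j] * djk) / size_new
        for pair in list(dist):
            if i in pair or j in pair:
                del dist[pair]
        del clusters[i], clusters[j], sizes[i], sizes[j], keys[i], keys[j]
        clusters[next_id] = node
        sizes[next_id] = size_new
        keys[next_id] = min(node.leaf_labels())
        for k, v in new_dist.items():
            dist[tuple(sorted((k, next_id)))] = v
        next_id += 1
    (root,) = clusters.values()
    return UPGMATree(root=root, labels=list(d.labels))


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def to_newick(t: UPGMATree | TreeNode, with_support: bool = True) -> str:
    """Serialize a tree to Newick, branch lengths from node heights.

    Bootstrap supports, when present, are written as internal node labels.
    """
    root = t.root if isinstance(t, UPGMATree) else t

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            body = f"({inner})"
            if with_support and node.support is not None:
                body += _fmt(node.support)
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - node.height)}"

    return render(root, None) + ";"


@dataclass(frozen=True)
class PCAResult:
    """Principal components of a samples x variables matrix."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray
    eigenvalues: np.ndarray


def pca(data: pd.DataFrame, standardize: bool = False) -> PCAResult:
    """PCA via singular value decomposition of the centered matrix.

    ``standardize`` divides each variable by its (ddof=1) standard
    deviation; zero-variance variables are dropped with a warning.  The
    sign of each component is fixed so that its largest-magnitude loading
    is positive.  Eigenvalues are the variances along components
    (``s^2/(n-1)``); ``explained_pct`` their percentage shares.
    """
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    x = data.to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("PCA input contains missing values")
    cols = list(data.columns)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"dropping zero-variance variable(s): {dropped}")
            x = x[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
        x = x / x.std(axis=0, ddof=1)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n - 1, len(cols))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| positive per component
    for c in range(k):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    eig = s**2 / (n - 1)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=data.index, columns=comp),
        loadings=pd.DataFrame(vt.T, index=cols, columns=comp),
        explained_pct=pct,
        eigenvalues=eig,
    )


class HeatmapScale(str, enum.Enum):
    MINUS1_1 = "minus1_1"
    ZSCORE = "zscore"


@dataclass(frozen=True)
class HeatmapLayout:
    """Scaled matrix plus dendrogram row/column orders for a heatmap."""

    scaled: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_tree: UPGMATree
    col_tree: UPGMATree


def heatmap_prepare(
    data: pd.DataFrame, scale: HeatmapScale | str = HeatmapScale.MINUS1_1
) -> HeatmapLayout:
    """Scale variables and derive clustered row/column orders.

    ``minus1_1`` maps each variable's min/max to -1/1 (a constant variable
    maps to 0 with a warning); ``zscore`` standardizes.  Orders come from
    UPGMA on Euclidean distances of the scaled matrix.
    """
    scale = HeatmapScale(scale)
    scaled = data.astype(float).copy()
    for col in scaled.columns:
        v = scaled[col]
        if scale is HeatmapScale.MINUS1_1:
            rng = v.max() - v.min()
            if rng == 0:
                warnings.warn(f"constant variable {col!r} mapped to 0")
                scaled[col] = 0.0
            else:
                scaled[col] = 2.0 * (v - v.min()) / rng - 1.0
        else:
            sd = v.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                warnings.warn(f"constant variable {col!r} mapped to 0")
                scaled[col] = 0.0
            else:
                scaled[col] = (v - v.mean()) / sd
    row_tree = upgma(DistanceMatrix.euclidean(scaled))
    col_tree = upgma(DistanceMatrix.euclidean(scaled.T))
    return HeatmapLayout(
        scaled=scaled,
        row_order=row_tree.leaf_labels(),
        col_order=col_tree.leaf_labels(),
        row_tree=row_tree,
        col_tree=col_tree,
    )
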