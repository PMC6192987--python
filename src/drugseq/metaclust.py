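"""Meta-hierarchical clustering across datasets on Fisher-z similarities.

To compare how several platforms (datasets) organize the same samples, each
dataset contributes a Pearson correlation matrix between samples. The
correlations are variance-stabilized with the Fisher transform
``z = atanh(r)`` (sampling variance ~ 1/(n-3) for n features), combined per
sample pair across datasets with a DerSimonian-Laird random-effects summary,
and the combined similarities are clustered by average linkage performed in
similarity space (merge the most similar pair; cluster-cluster similarity is
the unweighted mean of member-pair z values). Dendrogram display heights are
``tanh`` of the linkage scores, i.e. correlations again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

EPS = 1e-6


class AlignmentError(ValueError):
    """Datasets do not share sample labels / row universe."""


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------


def fisher_z(r):
    """z = atanh(r); |r| within EPS of 1 is clamped before the transform."""
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) > 1).any():
        raise ValueError("|r| > 1 outside the correlation domain")
    clamped = np.clip(arr, -1 + EPS, 1 - EPS)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(r) else out


def fisher_z_inverse(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Fisher-z similarities between samples from one dataset.

    ``z`` is a symmetric labels x labels DataFrame; the diagonal is +inf
    (self-similarity sentinel, excluded from all combination and linkage
    means). ``n`` is the effective sample size (number of features behind
    each correlation), giving per-pair variance 1/(n-3).
    """

    z: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        if list(self.z.index) != list(self.z.columns):
            raise AlignmentError("similarity matrix index != columns")
        arr = self.z.to_numpy(dtype=float)
        off = ~np.eye(len(arr), dtype=bool)
        if len(arr) > 1 and not np.allclose(arr[off], arr.T[off], equal_nan=True):
            raise AlignmentError("similarity matrix not symmetric")

    @property
    def labels(self) -> list[str]:
        return list(self.z.index)


def similarity_from_data(data: pd.DataFrame) -> SimilarityMatrix:
    """Fisher-z Pearson similarity between columns (samples) of a features x
    samples matrix."""
    r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, np.inf)
    return SimilarityMatrix(
        pd.DataFrame(z, index=data.columns, columns=data.columns), n=data.shape[0]
    )


def combine_similarities(matrices: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """DerSimonian-Laird random-effects combination of per-dataset z values.

    For each sample pair the k per-dataset estimates z_i with within-dataset
    variances 1/(n_i - 3) are combined: the heterogeneity Q statistic yields
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) with w_i = n_i - 3,
    and the summary is the inverse-variance weighted mean with weights
    1 / (1/w_i + tau^2). A single dataset is returned unchanged.
    """
    if not matrices:
        raise ValueError("no similarity matrices to combine")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise AlignmentError("sample labels differ between datasets")
    if len(matrices) == 1:
        return SimilarityMatrix(matrices[0].z.copy(), matrices[0].n)
    for m in matrices:
        if m.n < 4:
            raise ValueError("each dataset needs n >= 4 features for 1/(n-3) variance")

    z_stack = np.stack([m.z.to_numpy(dtype=float) for m in matrices])  # k x s x s
    # neutralize the +inf self-similarity sentinel during arithmetic
    diag = np.eye(z_stack.shape[1], dtype=bool)
    z_stack[:, diag] = 0.0
    w = np.array([m.n - 3 for m in matrices], dtype=float)[:, None, None]
    k = len(matrices)

    sw = w.sum(axis=0)
    z_fe = (w * z_stack).sum(axis=0) / sw
    Q = (w * (z_stack - z_fe[None]) ** 2).sum(axis=0)
    c = sw - (w**2).sum(axis=0) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.maximum(0.0, (Q - (k - 1)) / c)
    w_star = 1.0 / (1.0 / w + tau2[None])
    combined = (w_star * z_stack).sum(axis=0) / w_star.sum(axis=0)
    np.fill_diagonal(combined, np.inf)
    return SimilarityMatrix(
        pd.DataFrame(combined, index=labels, columns=labels),
        n=int(sum(m.n for m in matrices)),
    )


# ---------------------------------------------------------------------------
# average linkage in similarity space
# ---------------------------------------------------------------------------


@dataclass
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    linkage_z: float
    height_r: float


@dataclass
class MetaDendrogram:
    """Sequence of merges; heights are correlations tanh(linkage z)."""

    merges: list[Merge]
    labels: list[str]

    def leaf_order(self) -> list[str]:
        """Leaf ordering implied by the merge sequence (left before right)."""
        order: dict[tuple[str, ...], list[str]] = {(l,): [l] for l in self.labels}
        for m in self.merges:
            order[m.left + m.right] = order[m.left] + order[m.right]
        if not self.merges:
            return list(self.labels)
        return order[self.merges[-1].left + self.merges[-1].right]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "left": "|".join(m.left),
                    "right": "|".join(m.right),
                    "linkage_z": m.linkage_z,
                    "height_r": m.height_r,
                }
                for m in self.merges
            ]
        )

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Cluster labels after undoing the last ``n_clusters - 1`` merges."""
        if not 1 <= n_clusters <= len(self.labels):
            raise ValueError("invalid cluster count")
        clusters = [(l,) for l in self.labels]
        for m in self.merges[: len(self.labels) - n_clusters]:
            clusters = [c for c in clusters if c not in (m.left, m.right)]
            clusters.append(m.left + m.right)
        out = {}
        for i, c in enumerate(clusters):
            for label in c:
                out[label] = i
        return out

    def to_newick(self) -> str:
        """Newick with branch lengths on a 1 - r height scale (viewer friendly)."""
        height: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.labels}
        newick: dict[tuple[str, ...], str] = {(l,): l for l in self.labels}
        key = None
        for m in self.merges:
            h = 1.0 - m.height_r
            key = m.left + m.right
            parts = []
            for child in (m.left, m.right):
                blen = max(h - height[child], 0.0)
                parts.append(f"{newick[child]}:{blen:.6g}")
            newick[key] = "(" + ",".join(parts) + ")"
            height[key] = h
        if key is None:
            key = (self.labels[0],)
        return newick[key] + ";"


def meta_average_linkage(combined: SimilarityMatrix) -> MetaDendrogram:
    """Agglomerate samples by maximum combined z with unweighted-mean updates.

    Ties are broken by the lexicographically smallest (left, right) cluster
    label pair, making the result deterministic and invariant to input row
    order. Linkage scores are non-increasing (average-linkage monotonicity);
    display heights are ``tanh`` of the scores.
    """
    labels = combined.labels
    if len(labels) < 2:
        raise ValueError("need >= 2 samples")
    arr = combined.z.to_numpy(dtype=float).copy()
    off = ~np.eye(len(arr), dtype=bool)
    if not np.isfinite(arr[off]).all():
        raise ValueError("non-finite off-diagonal similarity")

    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    sizes = {(l,): 1 for l in labels}
    sim = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            sim[((labels[i],), (labels[j],))] = arr[i, j]

    def get(a, b):
        return sim[(a, b)] if (a, b) in sim else sim[(b, a)]

    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                key = (min(a, b), max(a, b))
                cand = (-get(a, b), key)
                if best is None or cand < best:
                    best = cand
        (_, (a, b)) = best
        zlink = get(a, b)
        merged = a + b
        for c in clusters:
            if c in (a, b):
                continue
            s = (sizes[a] * get(a, c) + sizes[b] * get(b, c)) / (sizes[a] + sizes[b])
            sim[(merged, c)] = s
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(merged)
        sizes[merged] = sizes[a] + sizes[b]
        merges.append(
            Merge(left=a, right=b, linkage_z=float(zlink), height_r=float(np.tanh(zlink)))
        )
    return MetaDendrogram(merges, labels)


# ---------------------------------------------------------------------------
# pooled row ordering
# ---------------------------------------------------------------------------


def pooled_row_order(matrices: Sequence[pd.DataFrame]) -> list[str]:
    """Leaf order of the rows clustered once on the column-pooled matrix.

    All matrices must share the same row universe; the pooled (column
    concatenated) matrix is clustered with the similarity-space average
    linkage on Fisher-z row correlations, and the resulting leaf order is
    meant to be applied unchanged to each per-dataset display matrix.
    """
    if not matrices:
        raise AlignmentError("no matrices")
    rows = set(matrices[0].index)
    for m in matrices[1:]:
        if set(m.index) != rows:
            raise AlignmentError("row universe mismatch between datasets")
    ordered = sorted(rows)
    pooled = pd.concat([m.loc[ordered] for m in matrices], axis=1)
    if len(ordered) == 1:
        return ordered
    sim = similarity_from_data(pooled.T)  # rows become samples
    dend = meta_average_linkage(sim)
    return dend.leaf_order()
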