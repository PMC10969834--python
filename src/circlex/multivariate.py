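"""Sample-level clustering and ordination.

Hierarchical clustering uses the correlation distance d = 1 - Pearson r
between sample profiles with UPGMA (average) linkage; PCA is SVD-based
on feature-centered data. A mean-silhouette separation score quantifies
how well a labeling is separated in a given score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .containers import ConfigError


@dataclass
class Dendrogram:
    """UPGMA merge tree over samples.

    ``linkage`` is the scipy linkage matrix; leaf ids index into
    ``labels``. Average linkage on a correlation-derived distance may
    produce height inversions; they are flagged, not forbidden.
    """

    linkage: np.ndarray
    labels: list[str]
    metric: str = "pearson"
    method: str = "average"

    @property
    def has_inversions(self) -> bool:
        return bool((np.diff(self.linkage[:, 2]) < -1e-12).any())

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def top_split(self) -> tuple[set[str], set[str]]:
        """Leaf sets of the two clusters below the root merge."""
        assign = self.cut(2)
        a = {s for s, c in assign.items() if c == 1}
        b = {s for s, c in assign.items() if c == 2}
        return a, b

    def to_newick(self) -> str:
        n = len(self.labels)

        def rec(node: int) -> tuple[str, float]:
            if node < n:
                return self.labels[node], 0.0
            row = self.linkage[node - n]
            height = float(row[2]) / 2.0
            ls, lh = rec(int(row[0]))
            rs, rh = rec(int(row[1]))
            return f"({ls}:{height - lh:.6g},{rs}:{height - rh:.6g})", height

        s, _ = rec(2 * n - 2)
        return s + ";"


def correlation_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of samples with distance 1 - Pearson r.

    Columns are samples. Samples are sorted lexicographically first so
    the result is invariant to input column order (deterministic
    tie-break by sample id).
    """
    if matrix.shape[1] < 2:
        raise ConfigError("need at least 2 samples to cluster")
    matrix = matrix[sorted(matrix.columns)]
    vals = matrix.to_numpy(float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = matrix.columns[sd == 0][0]
        raise ConfigError(f"zero-variance sample '{bad}'")
    corr = np.corrcoef(vals.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=[str(c) for c in matrix.columns])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # features x components


def pca(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    subset: str = "all",
    n_components: int | None = None,
) -> PCAResult:
    """Centered SVD-based PCA of samples over a gene subset.

    ``subset`` selects 'all', 'autosomal' or 'chrX' features via the
    annotation. Component signs are fixed by making each component's
    largest-magnitude loading positive; variance fractions sum to 1.
    """
    if matrix.shape[1] < 2:
        raise ConfigError("need at least 2 samples")
    values = matrix
    if subset != "all":
        if annotation is None:
            raise ConfigError("annotation required for chromosome subsets")
        chrom = annotation.loc[values.index, "chromosome"]
        mask = chrom == "chrX" if subset == "chrX" else chrom != "chrX"
        values = values.loc[mask.to_numpy()]
        if values.empty:
            raise ConfigError(f"no features in subset '{subset}'")
    X = values.to_numpy(float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    fracs = s**2 / total if total > 0 else np.zeros_like(s)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(len(s)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    k = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=values.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=values.index, columns=comp_names)
    return PCAResult(scores=scores, variance_fractions=fracs, loadings=loadings)


def separation_score(sample_scores, labels) -> float:
    """Mean silhouette (Euclidean) of the labeling in the score space.

    Classes with fewer than 2 samples are excluded with a warning; at
    least two multi-sample classes must remain.
    """
    X = np.asarray(sample_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = pd.Series(list(labels))
    counts = y.value_counts()
    singles = counts.index[counts < 2].tolist()
    if singles:
        warnings.warn(f"excluding singleton classes from silhouette: {singles}")
        keep = ~y.isin(singles).to_numpy()
        X, y = X[keep], y[keep.nonzero()[0]]
    if y.nunique() < 2:
        raise ConfigError("need at least 2 classes with >= 2 samples each")
    return float(silhouette_score(X, y.to_numpy(), metric="euclidean"))
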