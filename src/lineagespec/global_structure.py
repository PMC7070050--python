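"""Sample-level structure: correlation, hierarchical clustering, PCA.

Expression is transformed (default log2(FPKM + 1)) before Pearson
correlation; clustering is average linkage on the 1 - r distance; PCA acts
on gene-centered transformed values with samples as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .quantify import ExpressionMatrix

__all__ = [
    "SampleStructure",
    "log2p1",
    "correlation_matrix",
    "hierarchical_cluster",
    "pca",
]


def log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@dataclass
class SampleStructure:
    correlation: pd.DataFrame
    linkage: np.ndarray | None = None
    labels: pd.Series | None = None
    pca_coords: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None


def correlation_matrix(em: ExpressionMatrix, transform=log2p1) -> pd.DataFrame:
    """Pearson r between samples on transformed FPKM across all genes."""
    if em.fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples for a correlation matrix")
    x = transform(em.fpkm.to_numpy())
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = em.fpkm.columns[sd == 0].tolist()
        raise ValueError(f"constant sample vector(s), r undefined: {bad}")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=em.fpkm.columns, columns=em.fpkm.columns)


def hierarchical_cluster(
    r: pd.DataFrame, k: int
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering on the 1 - r distance, cut at k clusters.

    Returns the scipy linkage matrix and a label Series over samples.
    """
    n = r.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = 1.0 - r.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return link, pd.Series(labels, index=r.index, name="cluster")


def dendrogram_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string with merge heights."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist + length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    root = tree
    inner = ",".join(walk(ch, root.dist) for ch in (root.left, root.right))
    return f"({inner});"


def pca(
    em: ExpressionMatrix, transform=log2p1, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of gene-centered transformed FPKM; samples are observations.

    Returns (coordinates DataFrame with PC1.. columns, explained-variance
    fractions ordered non-increasing).
    """
    if em.fpkm.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = transform(em.fpkm.to_numpy())  # genes x samples
    nonconst = x.std(axis=1) > 0
    if nonconst.sum() < 2:
        raise ValueError("need at least 2 non-constant genes for PCA")
    x = x[nonconst]
    x = x - x.mean(axis=1, keepdims=True)  # center each gene
    n_samples = x.shape[1]
    if n_components is None:
        n_components = min(n_samples - 1, x.shape[0])
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x.T)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords = pd.DataFrame(coords, index=em.fpkm.columns, columns=cols)
    return coords, model.explained_variance_ratio_


def sample_structure(
    em: ExpressionMatrix, k: int, transform=log2p1
) -> SampleStructure:
    """Convenience wrapper running correlation, UHC at k, and PCA."""
    r = correlation_matrix(em, transform)
    link, labels = hierarchical_cluster(r, k)
    coords, evr = pca(em, transform)
    return SampleStructure(
        correlation=r,
        linkage=link,
        labels=labels,
        pca_coords=coords,
        explained_variance_ratio=evr,
    )
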