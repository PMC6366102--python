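"""Clustering-based evaluation of harmonization quality.

The protocol: cluster the (harmonized) sample columns hierarchically under
Euclidean distance, then ask whether flat cuts of the tree group samples
by biology or by experimental platform, quantified with the adjusted Rand
index against each label set.  Branch stability is assessed by a gene
bootstrap, and distribution-shape convergence toward the reference is
measured with per-sample Kolmogorov-Smirnov distances to the reference's
mean quantile profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import ks_2samp
from sklearn.metrics import adjusted_rand_score

from .core_io import ExpressionMatrix

__all__ = [
    "ClusteringEvaluation",
    "hierarchical_cluster",
    "cut_tree",
    "adjusted_rand_index",
    "bootstrap_support",
    "shape_diagnostics",
    "evaluate_clustering",
]

_LINKAGES = ("average", "complete", "ward")


def hierarchical_cluster(
    matrix: ExpressionMatrix, linkage_method: str = "average"
) -> np.ndarray:
    """Agglomerative clustering of sample columns under Euclidean distance.

    Returns the scipy linkage matrix (one row per merge).
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs >= 2 samples")
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage_method must be one of {_LINKAGES}")
    X = matrix.values.to_numpy().T  # samples as observations
    return hierarchy.linkage(X, method=linkage_method, metric="euclidean")


def cut_tree(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat labels from cutting the tree into ``k`` clusters."""
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must label the same items")
    if labels_a.size < 2:
        raise ValueError("need >= 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def _branch_sets(linkage: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Sample-index set of every internal node, in merge order."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for i, (a, b, _, _) in enumerate(linkage):
        node = members[int(a)] | members[int(b)]
        members[n_leaves + i] = node
        out.append(node)
    return out


def bootstrap_support(
    matrix: ExpressionMatrix,
    linkage_method: str = "average",
    B: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Gene-bootstrap support for every branch of the sample dendrogram.

    Genes are resampled with replacement ``B`` times and the samples
    reclustered; a branch's support is the fraction of bootstrap trees
    containing exactly the same sample subset.  This is the plain
    bootstrap probability (no multiscale correction).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    base = hierarchical_cluster(matrix, linkage_method)
    n = matrix.n_samples
    branches = _branch_sets(base, n)
    hits = np.zeros(len(branches))
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy()
    for _ in range(B):
        idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
        boot = matrix.with_values(
            pd.DataFrame(arr[idx], columns=matrix.sample_ids)
        )
        blink = hierarchical_cluster(boot, linkage_method)
        bset = set(_branch_sets(blink, n))
        for i, br in enumerate(branches):
            if br in bset:
                hits[i] += 1
    labels = [",".join(sorted(matrix.sample_ids[i] for i in br)) for br in branches]
    return pd.Series(hits / B, index=labels)


def shape_diagnostics(
    matrix: ExpressionMatrix, Q: ExpressionMatrix, n_bins: int = 50
) -> pd.DataFrame:
    """Per-sample KS distance to the reference's mean quantile profile.

    The reference profile is the row-wise mean of Q's column-sorted
    values (the distribution every harmonized sample should share).  Also
    returns binned density curves for plotting, in ``attrs['density']``.
    """
    if matrix.n_genes != Q.n_genes:
        raise ValueError(
            f"gene-count mismatch: {matrix.n_genes} vs reference {Q.n_genes}"
        )
    ref = np.sort(Q.values.to_numpy(), axis=0).mean(axis=1)
    arr = matrix.values.to_numpy()
    ks = [
        float(ks_2samp(arr[:, j], ref).statistic) for j in range(matrix.n_samples)
    ]
    table = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "ks_to_reference": ks}
    ).set_index("sample_id")
    lo = min(arr.min(), ref.min())
    hi = max(arr.max(), ref.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    dens = {
        s: np.histogram(arr[:, j], bins=edges, density=True)[0]
        for j, s in enumerate(matrix.sample_ids)
    }
    dens["__reference__"] = np.histogram(ref, bins=edges, density=True)[0]
    table.attrs["density"] = pd.DataFrame(dens, index=edges[:-1])
    return table


def max_pairwise_ks(matrix: ExpressionMatrix) -> float:
    """Largest two-sample KS distance between any two sample columns."""
    arr = matrix.values.to_numpy()
    worst = 0.0
    for i in range(arr.shape[1]):
        for j in range(i + 1, arr.shape[1]):
            worst = max(worst, float(ks_2samp(arr[:, i], arr[:, j]).statistic))
    return worst


@dataclass
class ClusteringEvaluation:
    """Bundle of the platform-vs-biology clustering read-out."""

    linkage: np.ndarray
    labels_at_k: dict[int, np.ndarray]
    ari_platform: float
    ari_bio: float
    bootstrap_support: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def evaluate_clustering(
    matrix: ExpressionMatrix,
    linkage_method: str = "average",
    k_platform: int | None = None,
    k_bio: int = 2,
    bio_groups: dict[str, str] | None = None,
    bootstrap_B: int = 0,
    seed: int = 0,
) -> ClusteringEvaluation:
    """Score platform-led vs biology-led structure of the sample tree.

    The tree is cut at ``k_platform`` (default: number of distinct
    platforms) and scored against platform labels, and at ``k_bio``
    (default 2) against biological labels, optionally coarsened through
    ``bio_groups`` (e.g. mapping the mixture types to their dominant
    source: A, C -> "A-like"; B, D -> "B-like").
    """
    platforms = matrix.platform.to_numpy()
    bio = matrix.bio_label.to_numpy()
    if bio_groups is not None:
        bio = np.array([bio_groups.get(x, x) for x in bio])
    if k_platform is None:
        k_platform = len(np.unique(platforms))
    link = hierarchical_cluster(matrix, linkage_method)
    labels_p = cut_tree(link, k_platform)
    labels_b = cut_tree(link, k_bio)
    support = (
        bootstrap_support(matrix, linkage_method, bootstrap_B, seed)
        if bootstrap_B > 0
        else None
    )
    return ClusteringEvaluation(
        linkage=link,
        labels_at_k={k_platform: labels_p, k_bio: labels_b},
        ari_platform=adjusted_rand_index(labels_p, platforms),
        ari_bio=adjusted_rand_index(labels_b, bio),
        bootstrap_support=support,
    )
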