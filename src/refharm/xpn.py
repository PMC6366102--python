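"""One-sided cross-platform block-model transform.

A dataset P (the profiles being harmonized) is reshaped into the
distributional frame of a fixed reference dataset Q.  Both datasets are
described by the same partially linear block model

    x_gs = A[alpha(g), beta(s)] * b_g + c_g + sigma_g * eps_gs

where ``alpha`` clusters genes into K groups, ``beta`` clusters samples
into L groups, ``A`` holds block means, ``b``/``c`` are per-gene slope and
offset, and ``eps`` is unit-scale noise.  Gene clusters are shared between
P and Q; sample clusters come from one joint spherical (cosine-based)
k-means over the P and Q columns, which makes the grouping invariant to
per-sample scaling.  The transform keeps each P value's standardized
residual but replaces the systematic part (and the noise scale) by Q's:

    x*_gs = A_Q[alpha(g), beta(s)] * b_Q[g] + c_Q[g] + sigma_Q[g] * eps_hat

with eps_hat the standardized residual of x_gs under the P model.  Q is
never modified.  Clustering is stochastic; the final output averages the
transform over ``n_repeats`` independent clustering draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .core_io import LOG2, ExpressionMatrix

__all__ = [
    "HarmonizationConfig",
    "BlockModel",
    "cluster_genes",
    "cluster_samples_spherical",
    "fit_block_model",
    "transform_to_reference",
]


@dataclass(frozen=True)
class HarmonizationConfig:
    """Tunables of the block-model harmonization.

    Attributes
    ----------
    K, L
        Gene-cluster and sample-cluster counts.
    n_repeats
        Independent clustering repetitions averaged into the output.
    n_fit_iters, tol
        Alternating-fit iteration cap and convergence tolerance (max
        absolute parameter change).
    seed
        Base random seed; every stochastic step derives from it.
    n_restarts
        Random restarts per k-means (best objective wins).
    min_gene_overlap
        Minimum fraction of the working gene space a profile must cover.
    """

    K: int = 25
    L: int = 10
    n_repeats: int = 16
    n_fit_iters: int = 30
    tol: float = 1e-6
    seed: int = 0
    n_restarts: int = 3
    min_gene_overlap: float = 0.6

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError(f"cluster counts must be >= 1 (K={self.K}, L={self.L})")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def with_seed(self, seed: int) -> "HarmonizationConfig":
        return replace(self, seed=int(seed))


@dataclass
class BlockModel:
    """Fitted partially linear block model for one dataset.

    ``A`` is indexed by compacted cluster ids; ``gene_cluster_of`` /
    ``sample_cluster_of`` map the original labels to A's rows/columns.
    """

    gene_labels: np.ndarray  # original gene-cluster label per gene
    sample_labels: np.ndarray  # original sample-cluster label per sample
    A: np.ndarray  # (n_gene_clusters, n_sample_clusters) block means
    b: np.ndarray  # per-gene slope, mean 1 within each gene cluster
    c: np.ndarray  # per-gene offset, mean 0 within each gene cluster
    sigma: np.ndarray  # per-gene residual standard deviation
    gene_cluster_of: dict  # original gene label -> row of A
    sample_cluster_of: dict  # original sample label -> column of A

    def systematic(self, sample_labels: np.ndarray) -> np.ndarray:
        """Fitted systematic part A[alpha(g), beta(s)]*b_g + c_g.

        ``sample_labels`` may be any labels known to this model (e.g. the
        joint labels of another dataset's columns).
        """
        rows = np.array([self.gene_cluster_of[l] for l in self.gene_labels])
        try:
            cols = np.array([self.sample_cluster_of[l] for l in sample_labels])
        except KeyError as exc:
            raise KeyError(f"sample-cluster label {exc} unseen by this model") from exc
        return self.A[np.ix_(rows, cols)] * self.b[:, None] + self.c[:, None]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _zscore_rows(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    out = np.zeros_like(arr)
    np.divide(arr - mean, sd, out=out, where=sd > 0)
    return out


def _check_shared_genes(P: ExpressionMatrix, Q: ExpressionMatrix) -> None:
    if list(P.values.index) != list(Q.values.index):
        raise ValueError("P and Q must share an identical gene set and order")


def cluster_genes(
    P: ExpressionMatrix, Q: ExpressionMatrix, K: int, seed: int, n_restarts: int = 3
) -> np.ndarray:
    """Cluster genes on their z-scored profiles across P and Q samples.

    Each gene's feature vector is the concatenation of its expression
    profile over P's columns and over Q's columns, with every sample
    column standardized (z-scored across genes) first so that per-sample
    scale and offset do not drive the partition.  Genes cluster by their
    standardized level and shape in both datasets.  Deterministic given
    ``seed``; labels in 0..K-1 with no empty cluster.
    """
    _check_shared_genes(P, Q)
    if K > P.n_genes:
        raise ValueError(f"K={K} exceeds gene count {P.n_genes}")
    if K == 1:
        return np.zeros(P.n_genes, dtype=int)
    feats = np.hstack(
        [
            _zscore_rows(P.values.to_numpy().T).T,
            _zscore_rows(Q.values.to_numpy().T).T,
        ]
    )
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed % (2**31))
    return km.fit_predict(feats)


def _spherical_kmeans(
    units: np.ndarray, L: int, rng: np.random.Generator, n_restarts: int, n_iter: int = 50
) -> np.ndarray:
    """Plain spherical k-means on unit row vectors; returns labels 0..L-1."""
    n = units.shape[0]
    best_labels: np.ndarray | None = None
    best_score = -np.inf
    for _ in range(max(1, n_restarts)):
        centroids = units[rng.choice(n, size=L, replace=False)]
        labels = np.full(n, -1)
        for _ in range(n_iter):
            sims = units @ centroids.T
            new_labels = np.argmax(sims, axis=1)
            for k in range(L):
                members = new_labels == k
                if not members.any():
                    # re-seed an empty cluster with the worst-served point
                    worst = int(np.argmin(sims.max(axis=1)))
                    new_labels[worst] = k
                    members = new_labels == k
                ctr = units[members].sum(axis=0)
                norm = np.linalg.norm(ctr)
                centroids[k] = ctr / norm if norm > 0 else units[int(np.argmax(members))]
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        score = (units @ centroids.T).max(axis=1).sum()
        if score > best_score:
            best_score = score
            best_labels = labels.copy()
    assert best_labels is not None
    return best_labels


def cluster_samples_spherical(
    P: ExpressionMatrix, Q: ExpressionMatrix, L: int, seed: int, n_restarts: int = 3
) -> np.ndarray:
    """Joint cosine-based clustering of all P and Q sample columns.

    Columns are centered per gene with their own dataset's gene means (P
    columns by P means, Q columns by Q means) and scaled to unit
    Euclidean norm; spherical k-means assigns each to the centroid of
    highest cosine similarity.  Dataset-wise centering removes the
    systematic cross-dataset gene-mean offset — a pure platform artifact
    — so that samples group by their expression deviations (biology)
    rather than by which dataset they came from.  Every returned cluster
    contains at least one Q sample: a cluster with only P samples is
    merged into the cosine-nearest cluster that has Q support (the
    reference model must be able to describe every sample cluster).
    Labels cover P's columns first, then Q's.
    """
    _check_shared_genes(P, Q)
    XP = P.values.to_numpy()
    XQ = Q.values.to_numpy()
    X = np.hstack(
        [XP - XP.mean(axis=1, keepdims=True), XQ - XQ.mean(axis=1, keepdims=True)]
    )
    n_total = X.shape[1]
    if L > n_total:
        raise ValueError(f"L={L} exceeds total sample count {n_total}")
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    units = (X / norms[None, :]).T  # samples x genes, unit rows
    if L == 1:
        return np.zeros(n_total, dtype=int)
    rng = np.random.default_rng(seed)
    labels = _spherical_kmeans(units, L, rng, n_restarts)
    # repair: every cluster must contain at least one Q sample
    is_q = np.zeros(n_total, dtype=bool)
    is_q[P.n_samples :] = True
    centroids = np.zeros((L, units.shape[1]))
    occupied = np.zeros(L, dtype=bool)
    for k in range(L):
        members = labels == k
        if members.any():
            occupied[k] = True
            ctr = units[members].mean(axis=0)
            centroids[k] = ctr / max(np.linalg.norm(ctr), 1e-12)
    has_q = np.array([(is_q & (labels == k)).any() for k in range(L)])
    if not has_q.any():  # impossible when L <= n_Q, but stay safe
        raise ValueError("no cluster contains a reference sample")
    for k in np.flatnonzero(occupied & ~has_q):
        sims = centroids[has_q] @ centroids[k]
        target = np.flatnonzero(has_q)[int(np.argmax(sims))]
        labels[labels == k] = target
    return labels


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_block_model(
    X: np.ndarray,
    gene_labels: np.ndarray,
    sample_labels: np.ndarray,
    n_fit_iters: int = 30,
    tol: float = 1e-6,
) -> BlockModel:
    """Alternating least-squares fit of the block model to ``X`` (log2).

    Iterates: (1) block means ``A`` given (b, c) by weighted least squares;
    (2) per-gene ordinary least squares of the gene's row on its block-mean
    profile, giving (b_g, c_g); (3) renormalization within each gene
    cluster to the identifiability constraint mean(b)=1, mean(c)=0, folded
    into ``A`` so fitted values are unchanged.  Stops when the largest
    parameter change drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    gene_labels = np.asarray(gene_labels)
    sample_labels = np.asarray(sample_labels)
    if len(gene_labels) != n_genes or len(sample_labels) != n_samples:
        raise ValueError("cluster maps must cover all genes and samples")
    g_unique, g_idx = np.unique(gene_labels, return_inverse=True)
    s_unique, s_idx = np.unique(sample_labels, return_inverse=True)
    K, L = len(g_unique), len(s_unique)
    G = np.zeros((K, n_genes))
    G[g_idx, np.arange(n_genes)] = 1.0
    S = np.zeros((n_samples, L))
    S[np.arange(n_samples), s_idx] = 1.0
    n_per_scluster = S.sum(axis=0)

    b = np.ones(n_genes)
    c = np.zeros(n_genes)
    A = np.zeros((K, L))
    for _ in range(max(1, n_fit_iters)):
        A_old, b_old, c_old = A, b.copy(), c.copy()
        # (1) block means given (b, c)
        R = (X - c[:, None]) * b[:, None]
        num = G @ R @ S
        den = (G @ (b**2))[:, None] * n_per_scluster[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        # (2) per-gene OLS on the block-mean profile
        M = A[np.ix_(g_idx, s_idx)]
        m_mean = M.mean(axis=1)
        x_mean = X.mean(axis=1)
        m_var = (M * M).mean(axis=1) - m_mean**2
        cov = (M * X).mean(axis=1) - m_mean * x_mean
        degenerate = m_var <= 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            b = np.where(degenerate, 1.0, cov / np.where(degenerate, 1.0, m_var))
        c = x_mean - b * m_mean
        # (3) identifiability: mean(b)=1 and mean(c)=0 per gene cluster
        mb = (G @ b) / G.sum(axis=1)
        mc = (G @ c) / G.sum(axis=1)
        mb = np.where(np.abs(mb) < 1e-8, 1.0, mb)
        b = b / mb[g_idx]
        c = c - mc[g_idx] * b
        A = A * mb[:, None] + mc[:, None]
        delta = max(
            np.abs(A - A_old).max(), np.abs(b - b_old).max(), np.abs(c - c_old).max()
        )
        if delta < tol:
            break
    fitted = A[np.ix_(g_idx, s_idx)] * b[:, None] + c[:, None]
    sigma = (X - fitted).std(axis=1)
    return BlockModel(
        gene_labels=gene_labels,
        sample_labels=sample_labels,
        A=A,
        b=b,
        c=c,
        sigma=sigma,
        gene_cluster_of={l: i for i, l in enumerate(g_unique)},
        sample_cluster_of={l: j for j, l in enumerate(s_unique)},
    )


# ---------------------------------------------------------------------------
# The transform
# ---------------------------------------------------------------------------

def _transform_once(
    XP: np.ndarray,
    XQ: np.ndarray,
    alpha: np.ndarray,
    beta_P: np.ndarray,
    beta_Q: np.ndarray,
    n_fit_iters: int,
    tol: float,
) -> np.ndarray:
    model_P = fit_block_model(XP, alpha, beta_P, n_fit_iters, tol)
    model_Q = fit_block_model(XQ, alpha, beta_Q, n_fit_iters, tol)
    sys_P = model_P.systematic(beta_P)
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = np.where(
            model_P.sigma[:, None] > 0,
            (XP - sys_P) / np.where(model_P.sigma[:, None] > 0, model_P.sigma[:, None], 1.0),
            0.0,
        )
    sys_Q_frame = model_Q.systematic(beta_P)
    return sys_Q_frame + model_Q.sigma[:, None] * eps


def transform_to_reference(
    P: ExpressionMatrix, Q: ExpressionMatrix, config: HarmonizationConfig
) -> ExpressionMatrix:
    """Reshape dataset P into the block-model frame of the fixed Q.

    Runs ``config.n_repeats`` independent clustering draws (seeded
    ``config.seed + r``); each draws a shared gene clustering and a joint
    spherical sample clustering over P and Q columns, fits the block model
    separately on P and on Q (same gene clusters, same joint sample-cluster
    labels), and maps every P value into Q's frame keeping its standardized
    residual.  The output is the element-wise mean over repeats; Q is never
    modified.
    """
    _check_shared_genes(P, Q)
    if P.scale != LOG2 or Q.scale != LOG2:
        raise ValueError("transform_to_reference expects log2-scale matrices")
    if Q.n_samples < config.L:
        raise ValueError(f"Q needs >= L={config.L} samples, has {Q.n_samples}")
    XP = P.values.to_numpy()
    XQ = Q.values.to_numpy()
    nP = P.n_samples
    acc = np.zeros_like(XP)
    for r in range(config.n_repeats):
        rep_seed = int(config.seed + r) % (2**31)
        alpha = cluster_genes(P, Q, config.K, rep_seed, config.n_restarts)
        beta = cluster_samples_spherical(P, Q, config.L, rep_seed, config.n_restarts)
        acc += _transform_once(
            XP, XQ, alpha, beta[:nP], beta[nP:], config.n_fit_iters, config.tol
        )
    return P.with_values(acc / config.n_repeats)
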