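"""Semantic-alignment metrics between two embedding sets.

Two views of alignment: the Jaccard overlap of directed k-nearest-neighbor
graphs (k=50, cosine distance, matching the evaluation convention of the
multimodal-fusion literature), and the Kraskov-Stoegbauer-Grassberger
k-NN mutual-information estimator between the embedding spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.metrics.pairwise import cosine_distances

__all__ = ["AlignmentScore", "knn_graph", "jaccard_knn",
           "mutual_information", "alignment_score"]


@dataclass
class AlignmentScore:
    mi_nats: float
    jaccard: float
    k: int
    metric: str = "cosine"


def knn_graph(embeddings: np.ndarray, k: int = 50, metric: str = "cosine"
              ) -> set[tuple[int, int]]:
    """Directed edges to the k nearest neighbors of each point.

    Cosine distance, self excluded, ties broken deterministically by the
    lower index.
    """
    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    if metric != "cosine":
        raise ValueError("only cosine distance is supported")
    D = cosine_distances(X)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        # lexsort: primary key distance, secondary key index (tie-break)
        order = np.lexsort((idx, D[i]))[:k]
        edges.update((i, int(j)) for j in order)
    return edges


def jaccard_knn(graph_a: set[tuple[int, int]], graph_b: set[tuple[int, int]]
                ) -> float:
    """|E_a ∩ E_b| / |E_a ∪ E_b| over directed edges."""
    nodes_a = {i for i, _ in graph_a} | {j for _, j in graph_a}
    nodes_b = {i for i, _ in graph_b} | {j for _, j in graph_b}
    if nodes_a != nodes_b:
        raise ValueError("graphs must share the same node set")
    union = graph_a | graph_b
    if not union:
        return 0.0
    return len(graph_a & graph_b) / len(union)


def mutual_information(x: np.ndarray, y: np.ndarray, k: int = 3,
                       jitter: float = 1e-10, seed: int = 0) -> float:
    """KSG estimator (variant 1) of I(X; Y) in nats.

    Chebyshev (max-norm) balls in the joint space define the radius;
    marginal neighbor counts are taken strictly inside that radius.
    A tiny seeded jitter breaks ties in discrete-valued inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have the same number of rows")
    if n <= 2 * k:
        raise ValueError("need n > 2k samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    rng = np.random.default_rng(seed)
    x = x + jitter * rng.standard_normal(x.shape)
    y = y + jitter * rng.standard_normal(y.shape)
    z = np.hstack([x, y])
    tree_z = cKDTree(z)
    # distance to the k-th neighbor in the joint space (self excluded)
    dist, _ = tree_z.query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strict inequality: shrink the radius to just below eps
    radius = np.nextafter(eps, 0.0)
    tree_x = cKDTree(x)
    tree_y = cKDTree(y)
    nx = np.array([len(tree_x.query_ball_point(x[i], radius[i], p=np.inf)) - 1
                   for i in range(n)])
    ny = np.array([len(tree_y.query_ball_point(y[i], radius[i], p=np.inf)) - 1
                   for i in range(n)])
    mi = (digamma(k) + digamma(n)
          - np.mean(digamma(nx + 1) + digamma(ny + 1)))
    return float(mi)


def alignment_score(emb_a: np.ndarray, emb_b: np.ndarray, k: int = 50,
                    mi_k: int = 3, seed: int = 0) -> AlignmentScore:
    """Joint MI + kNN-graph Jaccard report for an embedding pair."""
    n = len(emb_a)
    k_eff = min(k, n - 1)
    ga = knn_graph(emb_a, k=k_eff)
    gb = knn_graph(emb_b, k=k_eff)
    return AlignmentScore(mutual_information(emb_a, emb_b, k=mi_k, seed=seed),
                          jaccard_knn(ga, gb), k_eff)
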