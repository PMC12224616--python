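"""Spot-neighborhood graphs.

Two constructions feed the graph-convolution branches:

* a **spatial graph**: each spot connects to its ``k1`` nearest spots in
  Euclidean coordinate space;
* an **embedding graph**: each spot connects to the ``k2`` spots whose
  low-dimensional embeddings have the highest Pearson correlation with its
  own.

Both select top-k per row (self excluded, ties broken toward the lowest spot
index so runs are reproducible), then symmetrize by logical OR. The
convolution operator is the symmetrically normalized adjacency with self
loops, D^{-1/2}(A+I)D^{-1/2}.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .containers import EmbeddingMatrix, NeighborGraph, SpotCoordinates
from .errors import ValidationError

DEFAULT_K_SPATIAL = 3
DEFAULT_K_EMBEDDING = 20


def _topk_rows(score: np.ndarray, k: int) -> sp.csr_matrix:
    """Directed kNN: per row, 1 at the k columns with the highest score.

    ``score`` has -inf on the diagonal. Stable argsort of the negated scores
    breaks ties toward the lowest column index.
    """
    n = score.shape[0]
    order = np.argsort(-score, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    knn = sp.csr_matrix(
        (np.ones(n * k), (rows, order.ravel())), shape=(n, n), dtype=np.float64
    )
    return knn


def _assemble(knn: sp.csr_matrix, k: int, kind: str) -> NeighborGraph:
    adj = knn.maximum(knn.T)  # logical OR for binary matrices
    adj.setdiag(0)
    adj.eliminate_zeros()
    return NeighborGraph(adjacency=adj.tocsr(), knn=knn, k=k, kind=kind)


def _clamp_k(k: int, n: int, name: str) -> int:
    if k < 1:
        raise ValidationError(f"{name} must be positive, got {k}")
    if k >= n:
        warnings.warn(f"{name}={k} >= N={n}; clamped to {n - 1}", stacklevel=3)
        return n - 1
    return k


def build_spatial_graph(p: SpotCoordinates, k1: int = DEFAULT_K_SPATIAL) -> NeighborGraph:
    """kNN graph over physical spot positions (Euclidean distance)."""
    n = p.n_spots
    if n < 2:
        raise ValidationError(f"need at least 2 spots, got {n}")
    k1 = _clamp_k(k1, n, "k1")
    d2 = cdist(p.coords, p.coords, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    return _assemble(_topk_rows(-d2, k1), k1, "spatial")


def pearson_matrix(e: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation of embedding rows.

    A constant row has undefined correlation; its entries (including the
    diagonal) are set to 0 with a warning rather than dividing by zero.
    """
    X = e.values if isinstance(e, EmbeddingMatrix) else np.asarray(e, float)
    if X.shape[1] < 2:
        raise ValidationError("Pearson correlation needs embedding dim >= 2")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant embedding row(s); correlations set to 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    return r


def build_embedding_graph(
    e: EmbeddingMatrix | np.ndarray, k2: int = DEFAULT_K_EMBEDDING
) -> NeighborGraph:
    """Top-k Pearson-correlation graph over embedding rows."""
    r = pearson_matrix(e)
    n = r.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 spots, got {n}")
    k2 = _clamp_k(k2, n, "k2")
    np.fill_diagonal(r, -np.inf)
    return _assemble(_topk_rows(r, k2), k2, "embedding")


def normalize_adjacency(g: NeighborGraph) -> NeighborGraph:
    """Attach the symmetric normalization D^{-1/2}(A+I)D^{-1/2}.

    Self loops are injected here (not at construction); D is the degree
    matrix of A+I, so no degree can be zero.
    """
    a_hat = (g.adjacency + sp.identity(g.n_spots, format="csr")).tocsr()
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    g.normalized_form = (d_inv_sqrt @ a_hat @ d_inv_sqrt).tocsr()
    return g


def export_edge_list(g: NeighborGraph, path) -> None:
    """Write the symmetrized edges as '<i>\\t<j>' lines, 0-based."""
    coo = g.adjacency.tocoo()
    with open(path, "w") as fh:
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\n")
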