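"""Spatial consistency constraint: mutual-p-NN sparsification + Laplacian loss.

The constraint keeps embedding-space neighbourhoods aligned with the
original similarity space.  A p-nearest-neighbour weight graph N marks
mutual neighbours with 1, one-sided neighbours with 0.5 and everything
else 0; the similarity matrix is sparsified elementwise by N; the loss is
a Tikhonov term on the embeddings plus weighted pairwise squared
distances, equivalently a graph-Laplacian trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeighbourWeightGraph",
    "SparseSimilarity",
    "p_nearest_graph",
    "sparsify",
    "scc_loss",
    "scc_loss_direct",
]

# The loss is defined by the plain double sum over ordered pairs
# sum_{i,r} S(i,r) ||z_i - z_r||^2, which equals 2 Tr(Z^T L Z); the trace
# implementation carries that factor so the two forms agree numerically.
TRACE_FACTOR = 2.0


@dataclass
class NeighbourWeightGraph:
    N: np.ndarray  # entries in {0, 0.5, 1}; symmetric; unit diagonal


@dataclass
class SparseSimilarity:
    S_hat_drug: np.ndarray
    S_hat_target: np.ndarray
    L_drug: np.ndarray
    L_target: np.ndarray
    D_drug: np.ndarray
    D_target: np.ndarray


def p_nearest_sets(S: np.ndarray, p: int) -> np.ndarray:
    """Boolean membership matrix: sets[i, j] iff j is in the p-set of i.

    The p-set of i holds the p indices with largest S(i, .), the node
    itself included (its self-similarity 1 is maximal); ties at the p-th
    place go to the lowest index so every set has exactly p members.
    """
    r = S.shape[0]
    if not (1 <= p <= r):
        raise ValueError(f"p must be in [1, {r}], got {p}")
    sets = np.zeros((r, r), dtype=bool)
    idx = np.arange(r)
    for i in range(r):
        order = np.lexsort((idx, -S[i]))[:p]
        sets[i, order] = True
    return sets


def p_nearest_graph(S: np.ndarray, p: int) -> NeighbourWeightGraph:
    """Mutual-p-NN weight graph: 1 if mutual, 0 if neither, 0.5 one-sided."""
    sets = p_nearest_sets(S, p)
    both = sets & sets.T
    neither = ~sets & ~sets.T
    N = np.where(both, 1.0, np.where(neither, 0.0, 0.5))
    return NeighbourWeightGraph(N=N)


def _laplacian(S_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    D = np.diag(S_hat.sum(axis=1))
    return D - S_hat, D


def sparsify(S_drug: np.ndarray, S_target: np.ndarray, p: int) -> SparseSimilarity:
    """Sparsify both similarity matrices and build their Laplacians."""
    N_d = p_nearest_graph(S_drug, p).N
    N_t = p_nearest_graph(S_target, p).N
    S_hat_d = N_d * S_drug
    S_hat_t = N_t * S_target
    L_d, D_d = _laplacian(S_hat_d)
    L_t, D_t = _laplacian(S_hat_t)
    return SparseSimilarity(S_hat_drug=S_hat_d, S_hat_target=S_hat_t,
                            L_drug=L_d, L_target=L_t,
                            D_drug=D_d, D_target=D_t)


def scc_loss(Z_drug: np.ndarray, Z_target: np.ndarray,
             sparse: SparseSimilarity, lambda_l: float, lambda_d: float,
             lambda_t: float, trace_factor: float = TRACE_FACTOR) -> float:
    """Spatial-consistency loss in the trace form.

    ``lambda_l (||Z^D||_F^2 + ||Z^T||_F^2)
    + lambda_d * c * Tr(Z^D' L^D Z^D) + lambda_t * c * Tr(Z^T' L^T Z^T)``
    with c = 2 so the value equals the ordered-pair double sum.
    """
    tik = lambda_l * (np.sum(Z_drug ** 2) + np.sum(Z_target ** 2))
    d_term = lambda_d * trace_factor * np.trace(Z_drug.T @ sparse.L_drug @ Z_drug)
    t_term = lambda_t * trace_factor * np.trace(Z_target.T @ sparse.L_target @ Z_target)
    return float(tik + d_term + t_term)


def scc_loss_direct(Z_drug: np.ndarray, Z_target: np.ndarray,
                    sparse: SparseSimilarity, lambda_l: float,
                    lambda_d: float, lambda_t: float) -> float:
    """Summation form of the loss (independent oracle for the trace form)."""
    tik = lambda_l * (np.sum(Z_drug ** 2) + np.sum(Z_target ** 2))
    d_term = 0.0
    S = sparse.S_hat_drug
    for i in range(Z_drug.shape[0]):
        for r in range(Z_drug.shape[0]):
            d_term += S[i, r] * np.sum((Z_drug[i] - Z_drug[r]) ** 2)
    t_term = 0.0
    T = sparse.S_hat_target
    for j in range(Z_target.shape[0]):
        for q in range(Z_target.shape[0]):
            t_term += T[j, q] * np.sum((Z_target[j] - Z_target[q]) ** 2)
    return float(tik + lambda_d * d_term + lambda_t * t_term)
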