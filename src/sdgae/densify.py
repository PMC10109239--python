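"""WKNKN densification of the interaction matrix and median thresholding.

Isolated nodes (drugs/targets without any known interaction) defeat graph
convolution, which aggregates over neighbourhoods.  The weighted K-nearest
known-neighbour step imputes each zero of Y from the interaction profiles
of the K most similar *known* drugs (and, symmetrically, targets), with
geometrically decaying weights.  Imputed values strictly between 0 and 1
form the multiset E; thresholding at the median of E yields the binary
matrix used to wire drug-target edges into the heterogeneous network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeighbourList",
    "DensifyResult",
    "k_nearest_known_neighbours",
    "wknkn",
    "discretize",
    "densify",
]


@dataclass
class NeighbourList:
    indices: np.ndarray  # known-node indices, descending similarity
    weights: np.ndarray  # similarity values, non-increasing


@dataclass
class DensifyResult:
    Y_dense: np.ndarray
    imputed_values: np.ndarray  # the multiset E, ascending
    e_median: float | None
    Y_DTI: np.ndarray


def k_nearest_known_neighbours(S: np.ndarray, known_mask: np.ndarray,
                               i: int, K: int) -> NeighbourList:
    """The K most similar known nodes to node i, self excluded.

    Descending similarity; ties broken by ascending index.  Fewer than K
    are returned when fewer known nodes exist; the empty list signals the
    caller to leave the profile untouched.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    mask = np.asarray(known_mask, dtype=bool).copy()
    mask[i] = False
    cand = np.flatnonzero(mask)
    if cand.size == 0:
        return NeighbourList(indices=np.empty(0, dtype=int),
                             weights=np.empty(0))
    sims = S[i, cand]
    order = np.lexsort((cand, -sims))[:K]
    picked = cand[order]
    return NeighbourList(indices=picked, weights=S[i, picked])


def _side_estimate(Y: np.ndarray, S: np.ndarray, known: np.ndarray,
                   K: int, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise neighbour estimate and a mask of rows that had neighbours."""
    r = Y.shape[0]
    est = np.zeros_like(Y, dtype=np.float64)
    has = np.zeros(r, dtype=bool)
    for i in range(r):
        nb = k_nearest_known_neighbours(S, known, i, K)
        if nb.indices.size == 0:
            continue
        decay = eta ** np.arange(nb.indices.size)
        denom = nb.weights.sum()
        if denom <= 0:
            continue
        est[i] = (decay * nb.weights) @ Y[nb.indices] / denom
        has[i] = True
    return est, has


def wknkn(Y: np.ndarray, S_drug: np.ndarray, S_target: np.ndarray,
          K: int, eta: float, agg: str = "mean") -> np.ndarray:
    """Weighted K-nearest-known-neighbour densification of Y.

    Drug-side estimate: for drug i with known neighbours d_1..d_K in
    descending similarity, ``sum_a eta^(a-1) S(i,d_a) Y(d_a, :) /
    sum_a S(i,d_a)``.  Target-side estimate symmetric over columns.  The
    two are combined (`agg`: mean, or max) and the result is
    ``max(Y, estimate)`` clipped to [0, 1]; original 1s are never lowered.
    """
    if not (0.0 < eta <= 1.0):
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    Y = np.asarray(Y, dtype=np.float64)
    known_drugs = Y.sum(axis=1) > 0
    known_targets = Y.sum(axis=0) > 0

    est_d, has_d = _side_estimate(Y, S_drug, known_drugs, K, eta)
    est_t_T, has_t = _side_estimate(Y.T, S_target, known_targets, K, eta)
    est_t = est_t_T.T

    d_mask = has_d[:, None] & np.ones(Y.shape[1], dtype=bool)[None, :]
    t_mask = np.ones(Y.shape[0], dtype=bool)[:, None] & has_t[None, :]
    both = d_mask & t_mask
    if agg == "mean":
        combined = np.where(both, 0.5 * (est_d + est_t),
                            np.where(d_mask, est_d,
                                     np.where(t_mask, est_t, 0.0)))
    elif agg == "max":
        combined = np.where(d_mask, est_d, 0.0)
        combined = np.maximum(combined, np.where(t_mask, est_t, 0.0))
    else:
        raise ValueError(f"agg must be 'mean' or 'max', got {agg!r}")
    return np.clip(np.maximum(Y, combined), 0.0, 1.0)


def discretize(Y: np.ndarray, Y_dense: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Threshold the densified matrix at the median imputed value.

    E collects the Y_dense entries strictly in (0, 1) at originally-zero
    positions.  The median of an even-sized E is the lower central value,
    so the threshold is always an attained imputation and ``>= e_median``
    is non-vacuous.  Empty E (nothing imputed) returns Y unchanged and
    ``None`` for the threshold.
    """
    Y = np.asarray(Y)
    Y_dense = np.asarray(Y_dense, dtype=np.float64)
    if np.any(Y_dense < Y - 1e-12):
        raise ValueError("Y_dense must dominate Y elementwise")
    vals = Y_dense[(Y == 0) & (Y_dense > 0) & (Y_dense < 1)]
    if vals.size == 0:
        return Y.astype(np.int64).copy(), None
    E = np.sort(vals)
    e_median = float(E[(E.size - 1) // 2])
    Y_DTI = (Y_dense >= e_median).astype(np.int64)
    Y_DTI[Y == 1] = 1
    return Y_DTI, e_median


def densify(Y: np.ndarray, S_drug: np.ndarray, S_target: np.ndarray,
            K: int, eta: float, agg: str = "mean") -> DensifyResult:
    """Full densification stage: WKNKN then median-threshold discretization."""
    Y = np.asarray(Y, dtype=np.float64)
    Y_dense = wknkn(Y, S_drug, S_target, K, eta, agg=agg)
    Y_DTI, e_median = discretize(Y, Y_dense)
    E = np.sort(Y_dense[(Y == 0) & (Y_dense > 0) & (Y_dense < 1)])
    return DensifyResult(Y_dense=Y_dense, imputed_values=E,
                         e_median=e_median, Y_DTI=Y_DTI)
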