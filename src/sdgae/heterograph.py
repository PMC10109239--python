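"""Heterogeneous drug-target network assembly and symmetric normalization.

Drugs occupy rows 0..m-1 and targets rows m..m+n-1.  The block adjacency
stacks the DDI network, the (densified) interaction matrix and the TTI
network; node features stack the fused similarities on the diagonal
blocks and the densified interaction profiles off-diagonal.  The GCN
operates on the self-looped, symmetrically degree-normalized adjacency
``A_bar = D^-1/2 (A + I) D^-1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeteroGraph",
    "build_adjacency",
    "build_features",
    "normalize_adjacency",
    "isolated_node_count",
    "build_heterograph",
    "export_edge_list",
]


@dataclass
class HeteroGraph:
    A_tilde: np.ndarray  # (m+n) x (m+n) block adjacency
    X_tilde: np.ndarray  # (m+n) x (m+n) node features
    A_bar: np.ndarray    # normalized adjacency
    m: int
    n: int


def build_adjacency(A_drug: np.ndarray, A_target: np.ndarray,
                    Y_DTI: np.ndarray) -> np.ndarray:
    """Block matrix [[A_drug, Y_DTI], [Y_DTI^T, A_target]]."""
    m, n = Y_DTI.shape
    if A_drug.shape != (m, m) or A_target.shape != (n, n):
        raise ValueError("block shape mismatch with Y_DTI")
    if not np.array_equal(A_drug, A_drug.T):
        raise ValueError("A_drug must be symmetric")
    if not np.array_equal(A_target, A_target.T):
        raise ValueError("A_target must be symmetric")
    return np.block([[np.asarray(A_drug, dtype=np.float64), Y_DTI],
                     [np.asarray(Y_DTI, dtype=np.float64).T, A_target]])


def build_features(S_drug: np.ndarray, S_target: np.ndarray,
                   Y_dense: np.ndarray) -> np.ndarray:
    """Block feature matrix [[S_drug, Y_dense], [Y_dense^T, S_target]]."""
    m, n = Y_dense.shape
    if S_drug.shape != (m, m) or S_target.shape != (n, n):
        raise ValueError("block shape mismatch with Y_dense")
    return np.block([[np.asarray(S_drug, dtype=np.float64), Y_dense],
                     [np.asarray(Y_dense, dtype=np.float64).T, S_target]])


def normalize_adjacency(A_tilde: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization D^-1/2 (A + I) D^-1/2.

    The self-loop guarantees every degree is positive, so isolated nodes
    stay well-defined (their row is the unit self-loop).
    """
    A_tilde = np.asarray(A_tilde, dtype=np.float64)
    if A_tilde.ndim != 2 or A_tilde.shape[0] != A_tilde.shape[1]:
        raise ValueError("A_tilde must be square")
    A_prime = A_tilde + np.eye(A_tilde.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_prime.sum(axis=1))
    return A_prime * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def isolated_node_count(Y_block: np.ndarray) -> tuple[int, int]:
    """(drugs, targets) with no interaction edge in the given DTI block."""
    drugs = int(np.sum(Y_block.sum(axis=1) == 0))
    targets = int(np.sum(Y_block.sum(axis=0) == 0))
    return drugs, targets


def build_heterograph(A_drug: np.ndarray, A_target: np.ndarray,
                      Y_DTI: np.ndarray, S_drug: np.ndarray,
                      S_target: np.ndarray, Y_dense: np.ndarray,
                      features: str = "similarity") -> HeteroGraph:
    """Assemble adjacency, features and normalized adjacency in one step.

    ``features="similarity"`` uses the fused-similarity/densified-profile
    blocks; ``"adjacency"`` feeds pure topology (X = A_tilde), kept as an
    ablation switch.
    """
    A_tilde = build_adjacency(A_drug, A_target, Y_DTI)
    if features == "similarity":
        X_tilde = build_features(S_drug, S_target, Y_dense)
    elif features == "adjacency":
        X_tilde = A_tilde.copy()
    else:
        raise ValueError(f"unknown features mode {features!r}")
    return HeteroGraph(A_tilde=A_tilde, X_tilde=X_tilde,
                       A_bar=normalize_adjacency(A_tilde),
                       m=Y_DTI.shape[0], n=Y_DTI.shape[1])


def export_edge_list(graph: HeteroGraph, path) -> None:
    """Write the heterogeneous network as a node-type-annotated edge TSV."""
    m = graph.m
    with open(path, "w") as fh:
        fh.write("u\tu_type\tv\tv_type\n")
        rows, cols = np.nonzero(np.triu(graph.A_tilde, k=1))
        for u, v in zip(rows, cols):
            ut = "drug" if u < m else "target"
            vt = "drug" if v < m else "target"
            ui = u if u < m else u - m
            vi = v if v < m else v - m
            fh.write(f"{ui}\t{ut}\t{vi}\t{vt}\n")
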