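"""Jaccard similarities from association networks and elementwise-max fusion.

Each binary association matrix (drug-disease, drug-side-effect, the DDI
network, ...) yields one similarity view: the Jaccard index of the two
rows' feature sets.  All views of a node type are fused by taking the
elementwise maximum, so the fused similarity dominates every view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import DtiDataset

__all__ = [
    "FusedSimilarity",
    "jaccard_similarity",
    "fuse_similarities",
    "build_fused",
    "interaction_view",
    "plot_similarity_heatmap",
]


@dataclass
class FusedSimilarity:
    S_drug: np.ndarray    # m x m
    S_target: np.ndarray  # n x n


def jaccard_similarity(B: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard index of the rows of a binary matrix.

    ``S[i, j] = |F_i & F_j| / |F_i | F_j|`` where ``F_i`` is the set of
    columns with a 1 in row i.  The 0/0 case (two empty feature sets) is 0
    off the diagonal and 1 on it: a node is maximally similar to itself,
    which nearest-neighbour routines rely on.
    """
    B = np.asarray(B, dtype=np.float64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return S


def interaction_view(A: np.ndarray) -> np.ndarray:
    """Jaccard view of an intra-type interaction network (DDI or TTI).

    Row i of the adjacency matrix is node i's feature set; the self-edge
    is excluded (the diagonal of A is zero by dataset invariant).
    """
    return jaccard_similarity(A)


def fuse_similarities(views: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise maximum over same-shaped similarity views."""
    if len(views) == 0:
        raise ValueError("need at least one similarity view")
    shape = views[0].shape
    for v in views[1:]:
        if v.shape != shape:
            raise ValueError(f"shape mismatch among views: {v.shape} vs {shape}")
    return np.maximum.reduce([np.asarray(v, dtype=np.float64) for v in views])


def build_fused(ds: DtiDataset) -> FusedSimilarity:
    """Fuse all drug views and all target views of a dataset.

    Drugs: chemical-structure similarity, DDI Jaccard, drug-disease
    Jaccard, drug-side-effect Jaccard.  Targets: sequence similarity,
    TTI Jaccard, target-disease Jaccard.
    """
    S_drug = fuse_similarities([
        ds.S_chemical,
        interaction_view(ds.A_drug),
        jaccard_similarity(ds.B_drug_disease),
        jaccard_similarity(ds.B_drug_sideeffect),
    ])
    S_target = fuse_similarities([
        ds.S_sequence,
        interaction_view(ds.A_target),
        jaccard_similarity(ds.B_target_disease),
    ])
    return FusedSimilarity(S_drug=S_drug, S_target=S_target)


def plot_similarity_heatmap(S: np.ndarray, indices=None, labels=None,
                            path=None, title=None):
    """Heatmap of a similarity submatrix for visual neighbourhood checks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if indices is not None:
        idx = np.asarray(indices)
        S = S[np.ix_(idx, idx)]
        if labels is not None:
            labels = [labels[i] for i in idx]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(S, vmin=0.0, vmax=1.0, cmap="viridis")
    fig.colorbar(im, ax=ax, label="similarity")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
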