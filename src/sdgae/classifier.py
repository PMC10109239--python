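"""Pairwise feature assembly and the LightGBM interaction classifier.

A drug-target pair is the concatenation of the two k-dimensional
embedding rows (length 2k); the label comes from the ORIGINAL interaction
matrix Y, never from the densified one — imputation informs the graph,
not the supervision.  All negative pairs are kept (no subsampling): the
boosted-tree ensemble handles the class imbalance.
"""

from __future__ import annotations

import numpy as np
from lightgbm import LGBMClassifier

from .autoencoder import EmbeddingSet
from .data_io import RunConfig

__all__ = [
    "pair_features",
    "all_pair_features",
    "assemble_training_set",
    "train_classifier",
    "predict_all",
]


def pair_features(Z: EmbeddingSet, i: int, j: int) -> np.ndarray:
    """Length-2k feature vector for the pair (drug i, target j)."""
    if not (0 <= i < Z.m) or not (0 <= j < Z.n):
        raise IndexError(f"pair index ({i}, {j}) out of range "
                         f"for {Z.m} drugs x {Z.n} targets")
    return np.concatenate([Z.Z_drug[i], Z.Z_target[j]])


def all_pair_features(Z: EmbeddingSet) -> np.ndarray:
    """(m*n) x 2k matrix of all pair features, drug-major (i*n + j) order."""
    m, n, k = Z.m, Z.n, Z.Z.shape[1]
    drug_part = np.repeat(Z.Z_drug, n, axis=0)
    target_part = np.tile(Z.Z_target, (m, 1))
    return np.hstack([drug_part, target_part])


def assemble_training_set(Z: EmbeddingSet, Y: np.ndarray,
                          train_pairs: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and labels for the given (i, j) training pairs.

    ``train_pairs`` is an integer array of shape (n_pairs, 2); labels are
    read from Y.  Raises if no positive pair is present.
    """
    pairs = np.asarray(train_pairs)
    X = np.hstack([Z.Z_drug[pairs[:, 0]], Z.Z_target[pairs[:, 1]]])
    y = Y[pairs[:, 0], pairs[:, 1]].astype(np.int64)
    if y.sum() == 0:
        raise ValueError("training set contains no positive pair")
    return X, y


def train_classifier(X: np.ndarray, y: np.ndarray,
                     cfg: RunConfig) -> LGBMClassifier:
    """Fit the gradient-boosted tree ensemble (binary cross-entropy)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train the classifier")
    model = LGBMClassifier(
        objective="binary",
        learning_rate=cfg.lr_gbdt,
        n_estimators=cfg.n_estimators,
        num_leaves=cfg.num_leaves,
        random_state=cfg.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    return model


def predict_all(model: LGBMClassifier, Z: EmbeddingSet) -> np.ndarray:
    """Score every drug-target pair; returns the m x n propensity matrix."""
    probs = model.predict_proba(all_pair_features(Z))[:, 1]
    return probs.reshape(Z.m, Z.n)
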