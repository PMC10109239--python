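"""Cross-validation protocol, ranking metrics and novel-interaction mode.

Known positive pairs are partitioned into folds; for each fold the test
positives are masked to zero in the working interaction matrix and the
entire representation stage (densification, heterogeneous graph,
embedding training) plus the classifier are refit on the masked data, so
no held-out interaction can leak through imputation or graph structure.
A pooled score matrix assigns each positive its held-out-fold score and
each negative the average of its per-fold scores; global and per-drug
metrics are computed from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .autoencoder import train_embeddings
from .classifier import assemble_training_set, predict_all, train_classifier
from .data_io import DtiDataset, RunConfig
from .densify import densify as _densify
from .heterograph import build_heterograph
from .scc import sparsify
from .similarity import FusedSimilarity, build_fused

__all__ = [
    "FoldSplit",
    "MetricReport",
    "make_folds",
    "run_cv",
    "roc_auc",
    "aupr",
    "top_omega_recall",
    "paired_t_test",
    "permuted_label_auc",
    "rank_novel",
    "compute_embeddings",
]

TOP_OMEGA_DEFAULTS = (0.05, 0.10, 0.15, 0.20, 0.30)


@dataclass
class FoldSplit:
    """Assignment of every known positive pair to one test fold."""
    pairs: np.ndarray        # (n_pos, 2) positive (drug, target) indices
    fold_of_pair: np.ndarray  # fold id per row of `pairs`
    n_folds: int

    def test_pairs(self, fold: int) -> np.ndarray:
        return self.pairs[self.fold_of_pair == fold]


@dataclass
class MetricReport:
    auc: float
    aupr: float
    per_fold_auc: list
    per_fold_aupr: list
    per_drug_auc: list
    per_drug_aupr: list
    top_omega: dict
    score_matrix: np.ndarray
    n_folds: int


def make_folds(Y: np.ndarray, n_folds: int, seed: int) -> FoldSplit:
    """Random near-equal partition of the positive pairs into folds."""
    pairs = np.argwhere(np.asarray(Y) == 1)
    if len(pairs) < n_folds:
        raise ValueError(f"only {len(pairs)} positives for {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    fold_of = np.empty(len(pairs), dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of[chunk] = f
    return FoldSplit(pairs=pairs, fold_of_pair=fold_of, n_folds=n_folds)


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision form)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined without positives")
    return float(average_precision_score(labels, scores))


def top_omega_recall(scores_row: np.ndarray, y_row: np.ndarray,
                     omega: float) -> float:
    """Fraction of a drug's true targets within the top-omega candidates.

    Candidates are ranked by descending score (ties by ascending index);
    the cut keeps ceil(omega * n_candidates) of them.
    """
    y_row = np.asarray(y_row)
    n_true = int(y_row.sum())
    if n_true == 0:
        raise ValueError("recall undefined for a drug without true targets")
    n_cand = len(scores_row)
    top = int(np.ceil(omega * n_cand))
    order = np.lexsort((np.arange(n_cand), -np.asarray(scores_row)))
    return float(y_row[order[:top]].sum() / n_true)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-drug metric lists."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length lists of size >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf, 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def permuted_label_auc(score_matrix: np.ndarray, Y: np.ndarray,
                       seed: int) -> float:
    """AUC of the scores against label-permuted ground truth (chance floor)."""
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.asarray(Y).ravel())
    return roc_auc(np.asarray(score_matrix).ravel(), labels)


def compute_embeddings(ds: DtiDataset, Y_working: np.ndarray,
                       cfg: RunConfig, fused: FusedSimilarity | None = None,
                       rng: np.random.Generator | None = None):
    """Representation stage on a working copy of Y (possibly fold-masked).

    Similarity fusion uses only the association/similarity matrices, never
    Y, so it is shared across folds; densification and the heterogeneous
    graph are rebuilt from the masked Y.
    """
    if fused is None:
        fused = build_fused(ds)
    if cfg.use_ddm:
        dres = _densify(Y_working, fused.S_drug, fused.S_target,
                        cfg.K, cfg.eta, agg=cfg.wknkn_agg)
        Y_DTI, Y_dense = dres.Y_DTI, dres.Y_dense
    else:
        Y_DTI = np.asarray(Y_working, dtype=np.int64)
        Y_dense = np.asarray(Y_working, dtype=np.float64)
    graph = build_heterograph(ds.A_drug, ds.A_target, Y_DTI,
                              fused.S_drug, fused.S_target, Y_dense,
                              features=cfg.features)
    sparse = sparsify(fused.S_drug, fused.S_target, cfg.p) if cfg.use_scc else None
    Z, state = train_embeddings(graph, sparse, cfg, rng=rng)
    return Z, state


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed + 1_000_003 * (fold + 1)) % (2 ** 31))


def run_cv(ds: DtiDataset, cfg: RunConfig,
           folds: FoldSplit | None = None) -> MetricReport:
    """Full cross-validated evaluation of the pipeline on one dataset."""
    Y = np.asarray(ds.Y)
    m, n = Y.shape
    if folds is None:
        folds = make_folds(Y, cfg.n_folds, cfg.seed)
    fused = build_fused(ds)

    pos_scores = np.full((m, n), np.nan)
    neg_sum = np.zeros((m, n))
    per_fold_auc, per_fold_aupr = [], []
    neg_mask = Y == 0

    for f in range(folds.n_folds):
        test = folds.test_pairs(f)
        Y_train = Y.copy().astype(np.float64)
        Y_train[test[:, 0], test[:, 1]] = 0.0
        assert np.all(Y_train[test[:, 0], test[:, 1]] == 0)  # leakage guard

        fold_cfg = cfg.replace(seed=_fold_seed(cfg.seed, f))
        Z, _ = compute_embeddings(ds, Y_train, fold_cfg, fused=fused)

        train_mask = np.ones((m, n), dtype=bool)
        train_mask[test[:, 0], test[:, 1]] = False
        train_pairs = np.argwhere(train_mask)
        X_tr, y_tr = assemble_training_set(Z, Y_train, train_pairs)
        model = train_classifier(X_tr, y_tr, fold_cfg)
        scores = predict_all(model, Z)

        pos_scores[test[:, 0], test[:, 1]] = scores[test[:, 0], test[:, 1]]
        neg_sum[neg_mask] += scores[neg_mask]

        fold_scores = np.concatenate([scores[test[:, 0], test[:, 1]],
                                      scores[neg_mask]])
        fold_labels = np.concatenate([np.ones(len(test)),
                                      np.zeros(int(neg_mask.sum()))])
        per_fold_auc.append(roc_auc(fold_scores, fold_labels))
        per_fold_aupr.append(aupr(fold_scores, fold_labels))

    pooled = np.where(neg_mask, neg_sum / folds.n_folds, pos_scores)
    assert not np.any(np.isnan(pooled))

    auc_g = roc_auc(pooled.ravel(), Y.ravel())
    aupr_g = aupr(pooled.ravel(), Y.ravel())

    per_drug_auc, per_drug_aupr, recalls = [], [], {w: [] for w in TOP_OMEGA_DEFAULTS}
    for i in range(m):
        if Y[i].sum() == 0 or Y[i].sum() == n:
            continue
        per_drug_auc.append(roc_auc(pooled[i], Y[i]))
        per_drug_aupr.append(aupr(pooled[i], Y[i]))
        for w in TOP_OMEGA_DEFAULTS:
            recalls[w].append(top_omega_recall(pooled[i], Y[i], w))
    top_omega = {w: float(np.mean(v)) for w, v in recalls.items()}

    return MetricReport(auc=auc_g, aupr=aupr_g,
                        per_fold_auc=per_fold_auc, per_fold_aupr=per_fold_aupr,
                        per_drug_auc=per_drug_auc, per_drug_aupr=per_drug_aupr,
                        top_omega=top_omega, score_matrix=pooled,
                        n_folds=folds.n_folds)


def rank_novel(ds: DtiDataset, cfg: RunConfig, top_n: int = 20,
               per_drug: int | None = None):
    """Rank all unobserved pairs by out-of-fold interaction propensity.

    Embeddings are trained once on the full interaction matrix (all known
    positives).  Negative pairs are folded; each fold's classifier is
    trained on all positives plus the remaining negatives and scores only
    its held-out negatives, so every candidate score is out-of-fold.
    Returns rows of (drug_id, target_id, score) sorted descending; with
    ``per_drug`` set, the top candidates per drug instead.
    """
    import pandas as pd

    Y = np.asarray(ds.Y)
    Z, _ = compute_embeddings(ds, Y.astype(np.float64), cfg)

    neg_pairs = np.argwhere(Y == 0)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(neg_pairs))
    scores = np.full((ds.m, ds.n), np.nan)
    pos_pairs = np.argwhere(Y == 1)
    for f, chunk in enumerate(np.array_split(order, cfg.n_folds)):
        held = neg_pairs[chunk]
        held_mask = np.zeros((ds.m, ds.n), dtype=bool)
        held_mask[held[:, 0], held[:, 1]] = True
        train_pairs = np.argwhere(~held_mask)
        fold_cfg = cfg.replace(seed=_fold_seed(cfg.seed, f))
        X_tr, y_tr = assemble_training_set(Z, Y, train_pairs)
        model = train_classifier(X_tr, y_tr, fold_cfg)
        all_scores = predict_all(model, Z)
        scores[held_mask] = all_scores[held_mask]

    rows = [(ds.drug_ids[i], ds.target_ids[j], scores[i, j], i, j)
            for i, j in neg_pairs]
    df = pd.DataFrame(rows, columns=["drug_id", "target_id", "score", "i", "j"])
    df = df.sort_values(["score", "i", "j"],
                        ascending=[False, True, True]).drop(columns=["i", "j"])
    if per_drug is not None:
        df = (df.groupby("drug_id", group_keys=False, sort=False)
                .head(per_drug).reset_index(drop=True))
        return df
    return df.head(top_n).reset_index(drop=True)
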