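"""Synthetic drug-target benchmark with planted cluster structure.

Emulates the full matrix collection of the public dataset at desk scale:
drugs and targets are partitioned into matched cluster pairs, interaction
probability is high within a matched pair and low elsewhere, intra-type
networks and association matrices share per-cluster feature blocks (so
Jaccard similarity recovers the clusters), and the precomputed similarity
matrices are noisy cluster indicators.  A configurable fraction of drugs
and targets have their interaction rows/columns zeroed to emulate the
isolated "unknown" nodes that motivate densification; the hidden
positives are retained as ground truth for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DtiDataset

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "ground_truth"]


@dataclass
class SynthConfig:
    """Generator settings; defaults define the desk-scale benchmark."""
    m: int = 60
    n: int = 80
    c: int = 4                       # matched drug/target cluster pairs
    pi_in: float = 0.3               # within-cluster interaction probability
    pi_out: float = 0.01             # background interaction probability
    assoc_rate: float = 0.4          # per-cluster association feature rate
    sim_noise: float = 0.1           # similarity jitter sd
    frac_unknown_drugs: float = 0.2
    frac_unknown_targets: float = 0.3
    n_diseases: int = 40
    n_sideeffects: int = 30
    intra_edge_rate: float = 0.3     # within-cluster DDI/TTI edge probability
    base_similarity: float = 0.2     # between-cluster similarity level
    seed: int = 7

    def __post_init__(self):
        if not (self.pi_in > self.pi_out):
            raise ValueError("pi_in must exceed pi_out")
        for name in ("frac_unknown_drugs", "frac_unknown_targets"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.c > min(self.m, self.n):
            raise ValueError(f"c={self.c} clusters infeasible for "
                             f"m={self.m}, n={self.n}")
        if self.c > min(self.n_diseases, self.n_sideeffects):
            raise ValueError("need at least one association feature per cluster")


@dataclass(eq=False)
class SyntheticDataset(DtiDataset):
    """A generated dataset plus the planted structure behind it."""
    drug_clusters: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    target_clusters: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    hidden_positives: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    Y_full: np.ndarray = field(default_factory=lambda: np.empty((0, 0), int))


def _cluster_assign(size: int, c: int, rng: np.random.Generator) -> np.ndarray:
    # round-robin base guarantees every cluster is non-empty, then shuffled
    labels = np.arange(size) % c
    rng.shuffle(labels)
    return labels


def _intra_network(labels: np.ndarray, rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    upper = np.triu(rng.random(same.shape) < rate, k=1) & np.triu(same, k=1)
    A = (upper | upper.T).astype(np.int64)
    return A

def _association(labels: np.ndarray, n_feat: int, c: int, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    # features are split into c blocks; rows draw mainly from their block
    blocks = np.arange(n_feat) % c
    B = np.zeros((labels.size, n_feat), dtype=np.int64)
    for i, g in enumerate(labels):
        own = blocks == g
        B[i, own] = rng.random(int(own.sum())) < rate
        B[i, ~own] = rng.random(int((~own).sum())) < 0.02
    return B


def _similarity(labels: np.ndarray, base: float, noise: float,
                rng: np.random.Generator) -> np.ndarray:
    same = (labels[:, None] == labels[None, :]).astype(np.float64)
    S = base + (1.0 - base) * same
    jitter = rng.normal(0.0, noise, size=S.shape)
    S = S + (jitter + jitter.T) / 2.0
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(cfg: SynthConfig) -> SyntheticDataset:
    """Generate a complete dataset; deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    gd = _cluster_assign(cfg.m, cfg.c, rng)
    gt = _cluster_assign(cfg.n, cfg.c, rng)

    match = gd[:, None] == gt[None, :]
    prob = np.where(match, cfg.pi_in, cfg.pi_out)
    Y_full = (rng.random((cfg.m, cfg.n)) < prob).astype(np.int64)

    A_drug = _intra_network(gd, cfg.intra_edge_rate, rng)
    A_target = _intra_network(gt, cfg.intra_edge_rate, rng)
    B_dd = _association(gd, cfg.n_diseases, cfg.c, cfg.assoc_rate, rng)
    B_ds = _association(gd, cfg.n_sideeffects, cfg.c, cfg.assoc_rate, rng)
    B_td = _association(gt, cfg.n_diseases, cfg.c, cfg.assoc_rate, rng)
    S_chem = _similarity(gd, cfg.base_similarity, cfg.sim_noise, rng)
    S_seq = _similarity(gt, cfg.base_similarity, cfg.sim_noise, rng)

    Y = Y_full.copy()
    hidden_drugs = rng.choice(cfg.m, size=int(round(cfg.frac_unknown_drugs * cfg.m)),
                              replace=False)
    hidden_targets = rng.choice(cfg.n, size=int(round(cfg.frac_unknown_targets * cfg.n)),
                                replace=False)
    Y[hidden_drugs, :] = 0
    Y[:, hidden_targets] = 0
    hidden = np.argwhere((Y_full == 1) & (Y == 0))

    return SyntheticDataset(
        drug_ids=[f"D{i:04d}" for i in range(cfg.m)],
        target_ids=[f"T{j:04d}" for j in range(cfg.n)],
        Y=Y, A_drug=A_drug, A_target=A_target,
        B_drug_disease=B_dd, B_drug_sideeffect=B_ds, B_target_disease=B_td,
        S_chemical=S_chem, S_sequence=S_seq,
        drug_clusters=gd, target_clusters=gt,
        hidden_positives=hidden, Y_full=Y_full,
    )


def ground_truth(ds: SyntheticDataset) -> np.ndarray:
    """The zeroed true positives, as (drug, target) index pairs."""
    return ds.hidden_positives
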