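"""Graph-convolutional autoencoder with adversarial regularization.

Encoder: two graph convolutions over the normalized adjacency,
``Z = tanh(A_bar sigmoid(A_bar X W1) W2)``.  Decoder: inner-product with
a sigmoid, ``A_hat(i, j) = sigmoid(z_i . z_j)``, trained to reconstruct
the block adjacency under a summed squared error.  The spatial
consistency loss (``scc`` module) is added to the encoder objective; a
small MLP discriminator pushes the embedding rows towards a standard
normal reference.  Everything is full-batch numpy with closed-form
gradients, so a fixed seed reproduces runs bit-for-bit on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, BCE_EPS, Discriminator, bce, glorot_uniform, sigmoid
from .data_io import RunConfig
from .heterograph import HeteroGraph
from .scc import SparseSimilarity, scc_loss

__all__ = [
    "EncoderParams",
    "EmbeddingSet",
    "TrainState",
    "gcn_encode",
    "decode",
    "reconstruction_loss",
    "bce",
    "discriminator_loss",
    "generator_loss",
    "train_embeddings",
]


@dataclass
class EncoderParams:
    W1: np.ndarray  # (m+n) x l
    W2: np.ndarray  # l x k

    @classmethod
    def init(cls, n_nodes: int, hidden_dim: int, embed_dim: int,
             rng: np.random.Generator) -> "EncoderParams":
        return cls(W1=glorot_uniform(rng, n_nodes, hidden_dim),
                   W2=glorot_uniform(rng, hidden_dim, embed_dim))


@dataclass
class EmbeddingSet:
    Z: np.ndarray  # (m+n) x k, entries in (-1, 1)
    m: int
    n: int

    @property
    def Z_drug(self) -> np.ndarray:
        return self.Z[: self.m]

    @property
    def Z_target(self) -> np.ndarray:
        return self.Z[self.m:]


@dataclass
class TrainState:
    """Per-epoch loss traces; the encoder loss is the bookkeeping sum
    of the reconstruction and spatial-consistency parts."""
    L_reconstitution: list = field(default_factory=list)
    L_spatial_consistency: list = field(default_factory=list)
    L_encoding: list = field(default_factory=list)
    L_D: list = field(default_factory=list)
    L_G: list = field(default_factory=list)


def _forward(A_bar: np.ndarray, AX: np.ndarray, params: EncoderParams):
    P = AX @ params.W1
    H = sigmoid(P)
    AH = A_bar @ H
    Q = AH @ params.W2
    Z = np.tanh(Q)
    return Z, (AX, H, AH)


def gcn_encode(A_bar: np.ndarray, X_tilde: np.ndarray,
               params: EncoderParams, m: int | None = None) -> EmbeddingSet:
    """Two-layer GCN forward pass; drug rows first, target rows last."""
    Z, _ = _forward(A_bar, A_bar @ X_tilde, params)
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite values in encoder output")
    n_nodes = A_bar.shape[0]
    m = n_nodes if m is None else m
    return EmbeddingSet(Z=Z, m=m, n=n_nodes - m)


def decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: sigmoid of the embedding Gram matrix."""
    return sigmoid(Z @ Z.T)


def reconstruction_loss(A_tilde: np.ndarray, A_hat: np.ndarray) -> float:
    """Summed (not averaged) squared entrywise reconstruction error."""
    if A_tilde.shape != A_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.sum((A_tilde - A_hat) ** 2))


def discriminator_loss(D: Discriminator, Z: np.ndarray,
                       Z_prime: np.ndarray) -> float:
    """Mean BCE of fake rows against 0 plus reference rows against 1."""
    return bce(D(Z), np.zeros(Z.shape[0])) + bce(D(Z_prime), np.ones(Z_prime.shape[0]))


def generator_loss(D: Discriminator, Z: np.ndarray) -> float:
    """Mean BCE of the discriminator's verdict on the embeddings against 1."""
    return bce(D(Z), np.ones(Z.shape[0]))


def _encoder_grads(A_bar, A_tilde, AX, params, Z, cache, m,
                   sparse: SparseSimilarity | None, cfg: RunConfig,
                   D: Discriminator | None):
    """Closed-form gradient of the encoder objective wrt W1, W2."""
    _, H, AH = cache
    n_nodes = Z.shape[0]

    A_hat = sigmoid(Z @ Z.T)
    G = 2.0 * (A_hat - A_tilde) * A_hat * (1.0 - A_hat)
    dZ = (G + G.T) @ Z

    if sparse is not None and cfg.use_scc:
        dZ += 2.0 * cfg.lambda_l * Z
        dZ[:m] += 2.0 * cfg.scc_trace_factor * cfg.lambda_d * (sparse.L_drug @ Z[:m])
        dZ[m:] += 2.0 * cfg.scc_trace_factor * cfg.lambda_t * (sparse.L_target @ Z[m:])

    if D is not None and cfg.use_gan:
        p, dcache = D.forward(Z)
        # generator wants D(z) -> 1; pre-sigmoid BCE gradient, clamped region flat
        inner = (p > BCE_EPS) & (p < 1.0 - BCE_EPS)
        dL_da3 = np.where(inner, (p - 1.0) / n_nodes, 0.0)
        _, dX = D.backward(dcache, dL_da3)
        dZ += dX

    dQ = dZ * (1.0 - Z ** 2)
    gW2 = AH.T @ dQ
    dH = A_bar @ (dQ @ params.W2.T)
    dP = dH * H * (1.0 - H)
    gW1 = AX.T @ dP
    return gW1, gW2


def train_embeddings(graph: HeteroGraph, sparse: SparseSimilarity | None,
                     cfg: RunConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[EmbeddingSet, TrainState]:
    """Joint training loop: alternating discriminator and encoder steps.

    Each epoch first updates the discriminator on the current embeddings
    against fresh standard-normal reference samples, then updates the
    encoder weights on reconstruction + spatial consistency + generator
    losses with Adam.  With the adversarial part disabled the loop is a
    deterministic full-batch gradient descent given the seed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_nodes = graph.A_bar.shape[0]
    params = EncoderParams.init(n_nodes, cfg.hidden_dim, cfg.embed_dim, rng)
    D = Discriminator(cfg.embed_dim, rng) if cfg.use_gan else None

    opt_enc = Adam([params.W1, params.W2], lr=cfg.lr_repr)
    opt_disc = Adam(D.params, lr=cfg.lr_repr) if D is not None else None

    AX = graph.A_bar @ graph.X_tilde
    state = TrainState()

    for epoch in range(cfg.epochs):
        Z, cache = _forward(graph.A_bar, AX, params)
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(f"training diverged at epoch {epoch}")

        if D is not None:
            Z_prime = rng.standard_normal(Z.shape)
            X_all = np.vstack([Z, Z_prime])
            y_all = np.concatenate([np.zeros(n_nodes), np.ones(n_nodes)])
            p, dcache = D.forward(X_all)
            inner = (p > BCE_EPS) & (p < 1.0 - BCE_EPS)
            dL_da3 = np.where(inner, (p - y_all) / n_nodes, 0.0)
            grads, _ = D.backward(dcache, dL_da3)
            L_D = bce(p[:n_nodes], 0.0) + bce(p[n_nodes:], 1.0)
            opt_disc.step(grads)
        else:
            L_D = float("nan")

        gW1, gW2 = _encoder_grads(graph.A_bar, graph.A_tilde, AX, params, Z,
                                  cache, graph.m, sparse, cfg, D)

        L_rec = reconstruction_loss(graph.A_tilde, decode(Z))
        if cfg.use_scc and sparse is not None:
            L_scc = scc_loss(Z[:graph.m], Z[graph.m:], sparse, cfg.lambda_l,
                             cfg.lambda_d, cfg.lambda_t, cfg.scc_trace_factor)
        else:
            L_scc = 0.0
        L_G = generator_loss(D, Z) if D is not None else float("nan")

        state.L_reconstitution.append(L_rec)
        state.L_spatial_consistency.append(L_scc)
        state.L_encoding.append(L_rec + L_scc)
        state.L_D.append(L_D)
        state.L_G.append(L_G)

        opt_enc.step([gW1, gW2])

    Z, _ = _forward(graph.A_bar, AX, params)
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite embeddings after training")
    return EmbeddingSet(Z=Z, m=graph.m, n=graph.n), state
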