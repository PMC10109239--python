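import numpy as np
import pytest

from sdgae._nn import Discriminator, sigmoid
from sdgae.autoencoder import (EncoderParams, bce, decode,
                               discriminator_loss, gcn_encode,
                               generator_loss, reconstruction_loss,
                               train_embeddings, _encoder_grads, _forward)
from sdgae.data_io import RunConfig
from sdgae.heterograph import build_heterograph
from sdgae.scc import scc_loss, sparsify


def _toy_graph(rng, m=4, n=3):
    Ad = np.triu((rng.random((m, m)) < 0.5).astype(float), 1)
    Ad = Ad + Ad.T
    At = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
    At = At + At.T
    Y = (rng.random((m, n)) < 0.4).astype(float)
    Sd = rng.random((m, m))
    Sd = (Sd + Sd.T) / 2
    np.fill_diagonal(Sd, 1.0)
    St = rng.random((n, n))
    St = (St + St.T) / 2
    np.fill_diagonal(St, 1.0)
    g = build_heterograph(Ad, At, Y.astype(np.int64), Sd, St, Y)
    sp = sparsify(Sd, St, p=2)
    return g, sp


class TestEncoderForward:
    def test_zero_w2_gives_zero_embeddings(self, rng):
        g, _ = _toy_graph(rng)
        params = EncoderParams(W1=rng.normal(size=(7, 5)), W2=np.zeros((5, 2)))
        Z = gcn_encode(g.A_bar, g.X_tilde, params, m=4).Z
        assert np.array_equal(Z, np.zeros((7, 2)))

    def test_embeddings_strictly_inside_unit_cube(self, rng):
        g, _ = _toy_graph(rng)
        params = EncoderParams.init(7, 5, 2, rng)
        Z = gcn_encode(g.A_bar, g.X_tilde, params, m=4).Z
        assert np.max(np.abs(Z)) < 1.0

    def test_matches_step_by_step_oracle(self, rng):
        g, _ = _toy_graph(rng, m=3, n=3)
        params = EncoderParams.init(6, 4, 2, rng)
        Z = gcn_encode(g.A_bar, g.X_tilde, params, m=3).Z
        # explicit two-product evaluation with scalar activations
        hidden = 1.0 / (1.0 + np.exp(-(g.A_bar @ g.X_tilde @ params.W1)))
        oracle = np.tanh(g.A_bar @ hidden @ params.W2)
        assert np.allclose(Z, oracle, atol=1e-10)

    def test_drug_target_view_split(self, rng):
        g, _ = _toy_graph(rng)
        emb = gcn_encode(g.A_bar, g.X_tilde, EncoderParams.init(7, 5, 2, rng), m=4)
        assert emb.Z_drug.shape == (4, 2) and emb.Z_target.shape == (3, 2)
        assert np.array_equal(np.vstack([emb.Z_drug, emb.Z_target]), emb.Z)


class TestDecoderAndLosses:
    def test_orthogonal_rows_decode_to_half(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert decode(Z)[0, 1] == pytest.approx(0.5)

    def test_decode_symmetric_and_diagonal_value(self):
        Z = np.array([[2.0, 0.0], [2.0, 0.0]])
        A_hat = decode(Z)
        assert np.allclose(A_hat, A_hat.T)
        assert A_hat[0, 1] == pytest.approx(1.0 / (1.0 + np.exp(-4.0)))

    def test_reconstruction_loss_values_and_oracle(self, rng):
        A = rng.random((5, 5))
        assert reconstruction_loss(A, A) == 0.0
        B = A.copy()
        B[1, 2] += 0.5
        assert reconstruction_loss(A, B) == pytest.approx(0.25)
        C = rng.random((5, 5))
        oracle = sum((A[i, j] - C[i, j]) ** 2 for i in range(5) for j in range(5))
        assert reconstruction_loss(A, C) == pytest.approx(oracle, abs=1e-12)

    def test_bce_closed_forms(self):
        assert bce(0.5, 1) == pytest.approx(np.log(2))
        assert bce(1.0, 1) == pytest.approx(0.0, abs=2e-7)
        assert bce(0.0, 1) == pytest.approx(-np.log(1e-7))

    def test_adversarial_losses_at_indifference(self, rng):
        # zero final layer -> D outputs exactly 0.5 everywhere
        D = Discriminator(3, rng)
        D.W3[:] = 0.0
        D.b3[:] = 0.0
        Z = rng.normal(size=(6, 3))
        Zp = rng.normal(size=(6, 3))
        assert discriminator_loss(D, Z, Zp) == pytest.approx(2 * np.log(2))
        assert generator_loss(D, Z) == pytest.approx(np.log(2))

    def test_adversarial_losses_match_elementwise_oracle(self, rng):
        D = Discriminator(3, rng)
        Z = rng.normal(size=(5, 3))
        Zp = rng.normal(size=(5, 3))
        p_fake, p_real = D(Z), D(Zp)
        oracle_d = np.mean([-np.log(1 - p) for p in p_fake]) + \
            np.mean([-np.log(p) for p in p_real])
        assert discriminator_loss(D, Z, Zp) == pytest.approx(oracle_d)
        oracle_g = np.mean([-np.log(p) for p in p_fake])
        assert generator_loss(D, Z) == pytest.approx(oracle_g)


class TestTraining:
    def _cfg(self, **kw):
        base = dict(hidden_dim=8, embed_dim=4, epochs=30, lr_repr=1e-2,
                    n_folds=2, seed=5)
        base.update(kw)
        return RunConfig.desk_profile(**base)

    def test_same_seed_reproduces_bitwise(self, rng):
        g, sp = _toy_graph(rng)
        Z1, _ = train_embeddings(g, sp, self._cfg())
        Z2, _ = train_embeddings(g, sp, self._cfg())
        assert np.array_equal(Z1.Z, Z2.Z)

    def test_bookkeeping_identity_every_epoch(self, rng):
        g, sp = _toy_graph(rng)
        _, state = train_embeddings(g, sp, self._cfg())
        total = np.array(state.L_encoding)
        parts = np.array(state.L_reconstitution) + np.array(state.L_spatial_consistency)
        assert np.allclose(total, parts, atol=1e-12)

    def test_scc_off_degenerates_to_reconstruction(self, rng):
        g, sp = _toy_graph(rng)
        _, state = train_embeddings(g, sp, self._cfg(use_scc=False))
        assert np.all(np.array(state.L_spatial_consistency) == 0.0)
        assert np.allclose(state.L_encoding, state.L_reconstitution)

    def test_loss_decreases_on_benchmark_subgraph(self, rng):
        g, sp = _toy_graph(rng, m=10, n=12)
        _, state = train_embeddings(g, sp, self._cfg(epochs=200))
        assert state.L_encoding[-1] < state.L_encoding[0]

    def test_gan_off_is_deterministic_descent(self, rng):
        g, sp = _toy_graph(rng)
        Z1, s1 = train_embeddings(g, sp, self._cfg(use_gan=False))
        Z2, s2 = train_embeddings(g, sp, self._cfg(use_gan=False))
        assert np.allclose(Z1.Z, Z2.Z, atol=1e-10)
        assert np.all(np.isnan(s1.L_D)) and np.all(np.isnan(s1.L_G))

    def test_backprop_matches_finite_differences(self, rng):
        g, sp = _toy_graph(rng, m=3, n=3)
        cfg = self._cfg(use_gan=False)
        params = EncoderParams.init(6, 5, 3, rng)
        AX = g.A_bar @ g.X_tilde

        def loss_fn():
            Z, _ = _forward(g.A_bar, AX, params)
            L = reconstruction_loss(g.A_tilde, decode(Z))
            L += scc_loss(Z[:3], Z[3:], sp, cfg.lambda_l, cfg.lambda_d,
                          cfg.lambda_t, cfg.scc_trace_factor)
            return L

        Z, cache = _forward(g.A_bar, AX, params)
        gW1, gW2 = _encoder_grads(g.A_bar, g.A_tilde, AX, params, Z, cache,
                                  3, sp, cfg, None)
        eps = 1e-6
        for (W, G) in ((params.W2, gW2), (params.W1, gW1)):
            for idx in [(0, 0), (1, 2), (2, 1)]:
                orig = W[idx]
                W[idx] = orig + eps
                up = loss_fn()
                W[idx] = orig - eps
                down = loss_fn()
                W[idx] = orig
                fd = (up - down) / (2 * eps)
                assert G[idx] == pytest.approx(fd, abs=1e-4, rel=1e-4)

    def test_generator_gradient_matches_finite_differences(self, rng):
        # the adversarial signal reaches the encoder weights through D
        g, sp = _toy_graph(rng, m=3, n=3)
        cfg = self._cfg(use_scc=False)
        params = EncoderParams.init(6, 5, 3, rng)
        D = Discriminator(3, rng)
        AX = g.A_bar @ g.X_tilde

        def loss_fn():
            Z, _ = _forward(g.A_bar, AX, params)
            return reconstruction_loss(g.A_tilde, decode(Z)) + \
                generator_loss(D, Z)

        Z, cache = _forward(g.A_bar, AX, params)
        gW1, gW2 = _encoder_grads(g.A_bar, g.A_tilde, AX, params, Z, cache,
                                  3, None, cfg, D)
        eps = 1e-6
        for idx in [(0, 0), (2, 2)]:
            orig = params.W2[idx]
            params.W2[idx] = orig + eps
            up = loss_fn()
            params.W2[idx] = orig - eps
            down = loss_fn()
            params.W2[idx] = orig
            fd = (up - down) / (2 * eps)
            assert gW2[idx] == pytest.approx(fd, abs=1e-4, rel=1e-4)
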