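"""GCN encoder: closed-form adjacency normalisation, scalar forward oracle,
gradient correctness, training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from mdlink import AssociationNetwork, GCNConfig, normalized_adjacency, reconstruct, train_gcn
from mdlink.gcn import (
    GCNEmbeddings,
    GCNParameters,
    _backward,
    _reconstruction_loss_and_grad,
    gcn_forward,
    init_parameters,
)


class TestNormalizedAdjacency:
    def test_single_entry(self):
        P = normalized_adjacency(np.array([[1, 0], [0, 0]]))
        assert P[0, 0] == pytest.approx(0.5)
        assert P[0, 1] == P[1, 0] == P[1, 1] == 0

    def test_zero_matrix(self):
        assert np.all(normalized_adjacency(np.zeros((3, 2))) == 0)

    def test_one_by_one(self):
        assert normalized_adjacency(np.array([[1]]))[0, 0] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_per_entry_closed_form(self, seed):
        """P[i,j] = Y[i,j] / sqrt((rowsum_i + 1)(colsum_j + 1)), exactly."""
        rng = np.random.default_rng(seed)
        Y = (rng.random((rng.integers(1, 8), rng.integers(1, 8))) < 0.4).astype(float)
        P = normalized_adjacency(Y)
        rows = Y.sum(axis=1)
        cols = Y.sum(axis=0)
        for i in range(Y.shape[0]):
            for j in range(Y.shape[1]):
                assert P[i, j] == pytest.approx(
                    Y[i, j] / np.sqrt((rows[i] + 1) * (cols[j] + 1)), abs=0
                )


def scalar_params() -> tuple[GCNParameters, GCNConfig]:
    """1x1 network, all weights 1, biases 0, h1=h2=1."""
    cfg = GCNConfig(h1=1, h2=1, layers=2, dropout=0.0, seed=0)
    ones = lambda: np.ones((1, 1))
    params = GCNParameters(
        W0_M=ones(), W0_D=ones(), b_M=np.zeros(1), b_D=np.zeros(1),
        W1=[ones(), ones()], W2=[ones(), ones()], b1=[np.zeros(1), np.zeros(1)],
    )
    return params, cfg


class TestForward:
    def test_zero_parameters_give_zero_embeddings(self):
        cfg = GCNConfig(h1=3, h2=2, dropout=0.0)
        params = init_parameters(4, 3, cfg)
        for a in params.flat():
            a[...] = 0.0
        emb = gcn_forward(params, cfg, np.eye(4), np.eye(3), np.zeros((4, 3)))
        assert np.all(emb.LM == 0) and np.all(emb.LD == 0)

    def test_default_output_widths(self):
        cfg = GCNConfig(dropout=0.0)
        params = init_parameters(10, 6, cfg)
        emb = gcn_forward(params, cfg, np.eye(10), np.eye(6), np.zeros((10, 6)))
        assert emb.LM.shape == (10, 128)
        assert emb.LD.shape == (6, 128)

    def test_scalar_chain_matches_hand_computation(self):
        """Single-node toy, every weight 1: follow the recurrences by hand."""
        params, cfg = scalar_params()
        P = normalized_adjacency(np.array([[1.0]]))  # 0.5
        # layer inputs: h_m = h_d = 1*1 + 0 = 1
        h_m = h_d = 1.0
        for _ in range(2):
            a_m = 0.5 * h_d
            a_d = 0.5 * h_m
            z_m = a_m + a_m * h_m  # W1 = W2 = 1, b = 0
            z_d = a_d + a_d * h_d
            h_m, h_d = max(z_m, 0.0), max(z_d, 0.0)
        emb = gcn_forward(params, cfg, np.ones((1, 1)), np.ones((1, 1)), P)
        assert emb.LM[0, 0] == pytest.approx(h_m)
        assert emb.LD[0, 0] == pytest.approx(h_d)

    def test_permutation_equivariance(self):
        """Permuting microbes (Y rows, FuM, W0_M rows) permutes LM identically."""
        rng = np.random.default_rng(3)
        n_m, n_d = 6, 4
        cfg = GCNConfig(h1=5, h2=3, dropout=0.0, seed=1)
        params = init_parameters(n_m, n_d, cfg)
        Y = (rng.random((n_m, n_d)) < 0.4).astype(float)
        FuM = rng.random((n_m, n_m))
        FuM = (FuM + FuM.T) / 2
        FuD = rng.random((n_d, n_d))
        FuD = (FuD + FuD.T) / 2
        emb = gcn_forward(params, cfg, FuM, FuD, normalized_adjacency(Y))

        perm = rng.permutation(n_m)
        import dataclasses

        params_p = dataclasses.replace(params, W0_M=params.W0_M[perm])
        emb_p = gcn_forward(
            params_p, cfg, FuM[np.ix_(perm, perm)], FuD,
            normalized_adjacency(Y[perm]),
        )
        assert np.allclose(emb_p.LM, emb.LM[perm])
        assert np.allclose(emb_p.LD, emb.LD)

    def test_eval_forward_is_pure(self):
        cfg = GCNConfig(h1=4, h2=2, dropout=0.5, seed=0)
        params = init_parameters(5, 3, cfg)
        rng = np.random.default_rng(0)
        Y = (rng.random((5, 3)) < 0.5).astype(float)
        args = (params, cfg, np.eye(5), np.eye(3), normalized_adjacency(Y))
        a = gcn_forward(*args)
        b = gcn_forward(*args)
        assert np.array_equal(a.LM, b.LM) and np.array_equal(a.LD, b.LD)


class TestReconstruct:
    def test_zero_embeddings_give_half(self):
        emb = GCNEmbeddings(LM=np.zeros((2, 3)), LD=np.zeros((2, 3)))
        assert np.allclose(reconstruct(emb), 0.5)

    def test_large_inner_product_saturates(self):
        emb = GCNEmbeddings(LM=np.array([[10.0]]), LD=np.array([[10.0]]))
        assert reconstruct(emb)[0, 0] == pytest.approx(expit(100.0))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruct(GCNEmbeddings(LM=np.zeros((1, 2)), LD=np.zeros((1, 3))))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """End-to-end analytic gradient vs central differences, small network."""
        rng = np.random.default_rng(0)
        n_m, n_d = 4, 3
        cfg = GCNConfig(h1=3, h2=2, dropout=0.0, seed=2)
        params = init_parameters(n_m, n_d, cfg)
        Y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        P = normalized_adjacency(Y)
        FuM = np.eye(n_m) * 0.8 + 0.1
        FuD = np.eye(n_d) * 0.8 + 0.1
        pos = np.argwhere(Y == 1)
        neg = np.argwhere(Y == 0)[:len(pos)]

        def loss_value() -> float:
            emb = gcn_forward(params, cfg, FuM, FuD, P)
            return _reconstruction_loss_and_grad(emb, pos, neg, "bce")[0]

        cache: dict = {}
        emb = gcn_forward(params, cfg, FuM, FuD, P, cache=cache)
        _, dLM, dLD = _reconstruction_loss_and_grad(emb, pos, neg, "bce")
        grads = _backward(params, cfg, cache, dLM, dLD)

        eps = 1e-6
        for arr, g in zip(params.flat(), grads.flat()):
            flat = arr.reshape(-1)
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up = loss_value()
                flat[k] = orig - eps
                down = loss_value()
                flat[k] = orig
                fd = (up - down) / (2 * eps)
                assert g.reshape(-1)[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


@pytest.fixture(scope="module")
def trained(benchmark, benchmark_bundle):
    net, _, _ = benchmark
    b = benchmark_bundle
    cfg = GCNConfig(epochs=300, seed=7)
    emb, hist = train_gcn(net, b.FuM, b.FuD, cfg, return_history=True)
    return net, emb, hist


class TestTraining:

    def test_loss_decreases(self, trained):
        _, _, hist = trained
        assert hist[-1] < hist[0]
        assert np.all(np.isfinite(hist))

    def test_moving_average_non_increasing(self, trained):
        _, _, hist = trained
        ma = np.convolve(hist, np.ones(50) / 50, mode="valid")
        assert ma[-1] <= ma[0] + 1e-6

    def test_embeddings_non_negative(self, trained):
        _, emb, _ = trained
        assert emb.LM.min() >= 0 and emb.LD.min() >= 0

    def test_reconstruction_separates_planted_edges(self, trained):
        net, emb, _ = trained
        Yh = reconstruct(emb)
        pos_mask = net.Y == 1
        assert Yh[pos_mask].mean() > Yh[~pos_mask].mean()

    def test_determinism(self, tiny_net):
        FuM = np.eye(2)
        FuD = np.eye(2)
        cfg = GCNConfig(h1=4, h2=2, epochs=20, seed=9)
        a = train_gcn(tiny_net, FuM, FuD, cfg)
        b = train_gcn(tiny_net, FuM, FuD, cfg)
        assert np.array_equal(a.LM, b.LM) and np.array_equal(a.LD, b.LD)

    def test_edgeless_network_rejected(self):
        net_Y = np.array([[0, 1], [1, 1]])
        net = AssociationNetwork(("m1", "m2"), ("d1", "d2"), net_Y)
        empty = net.with_masked_pairs({(0, 1), (1, 0), (1, 1)})
        with pytest.raises(ValueError, match="no edges"):
            train_gcn(empty, np.eye(2), np.eye(2), GCNConfig(epochs=1))
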