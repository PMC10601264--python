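"""Graph convolutions against brute-force oracles; attention pooling."""

import numpy as np
import pytest

from graphmil import (
    AttentionPool,
    ChebConv,
    ConvStack,
    GCNConv,
    GMMConv,
    build_adjacency,
    normalize_adjacency,
)
from graphmil.layers import load_checkpoint, normalize_adjacency_t, save_checkpoint
from graphmil.nn import Tensor


def random_adjacency(rng, n):
    return build_adjacency(rng.standard_normal((n, 3)), tau=None, sigma_a=1.5)


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------

def test_identity_adjacency_normalizes_to_identity():
    np.testing.assert_allclose(normalize_adjacency(np.eye(5)), np.eye(5))


def test_complete_graph_normalizes_to_uniform():
    n = 6
    np.testing.assert_allclose(normalize_adjacency(np.ones((n, n))),
                               np.full((n, n), 1 / n))


def test_normalized_spectrum_lies_in_unit_interval(rng):
    """Eigendecomposition oracle: |lambda| <= 1 for D^-1/2 A D^-1/2."""
    for _ in range(10):
        A = random_adjacency(rng, 8)
        eig = np.linalg.eigvalsh(normalize_adjacency(A))
        assert np.abs(eig).max() <= 1 + 1e-10


def test_asymmetric_input_rejected():
    A = np.eye(3)
    A[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        normalize_adjacency(A)


def test_tensor_normalization_matches_numpy(rng):
    A = random_adjacency(rng, 7)
    np.testing.assert_allclose(normalize_adjacency_t(Tensor(A)).data,
                               normalize_adjacency(A), atol=1e-12)


# ----------------------------------------------------------------------
# Chebyshev convolution
# ----------------------------------------------------------------------

def cheb_dense_oracle(X, A_norm, weights):
    """Materialize T_k(L_hat) explicitly and sum the filtered terms."""
    n = A_norm.shape[0]
    L = np.eye(n) - A_norm
    Ts = [np.eye(n), L]
    while len(Ts) < len(weights):
        Ts.append(2 * L @ Ts[-1] - Ts[-2])
    return sum(Ts[k] @ X @ W.data for k, W in enumerate(weights))


def test_order_one_filter_is_plain_linear_map(rng):
    conv = ChebConv(4, 3, order=1, rng=rng)
    X = rng.standard_normal((5, 4))
    A_norm = normalize_adjacency(random_adjacency(rng, 5))
    np.testing.assert_allclose(conv(Tensor(X), Tensor(A_norm)).data,
                               X @ conv.weights[0].data)


def test_zero_weights_give_zero_output(rng):
    conv = ChebConv(4, 3, order=3, rng=rng)
    for W in conv.weights:
        W.data[:] = 0.0
    X = rng.standard_normal((6, 4))
    A_norm = normalize_adjacency(random_adjacency(rng, 6))
    assert np.abs(conv(Tensor(X), Tensor(A_norm)).data).max() == 0.0


def test_cheb_matches_dense_polynomial_oracle(rng):
    for order in (2, 3, 4):
        conv = ChebConv(5, 4, order=order, rng=rng)
        X = rng.standard_normal((6, 5))
        A_norm = normalize_adjacency(random_adjacency(rng, 6))
        out = conv(Tensor(X), Tensor(A_norm)).data
        oracle = cheb_dense_oracle(X, A_norm, conv.weights)
        assert np.abs(out - oracle).max() < 1e-6


def test_invalid_order_rejected(rng):
    with pytest.raises(ValueError):
        ChebConv(4, 3, order=0, rng=rng)


# ----------------------------------------------------------------------
# Mixture-model convolution
# ----------------------------------------------------------------------

def gmm_loop_oracle(X, A, conv):
    """Per-node, per-kernel, per-neighbor triple loop."""
    n, K = A.shape[0], conv.n_kernels
    deg = (A > 0).sum(axis=1)
    u = deg**-0.5
    d_out = conv.weights[0].data.shape[1]
    h = np.zeros((n, d_out))
    for i in range(n):
        for k in range(K):
            mu, sig = conv.mu.data[k], np.exp(conv.log_sigma.data[k])
            for j in range(n):
                if A[i, j] <= 0:
                    continue
                w = np.exp(-0.5 * ((u[i] - mu[0]) ** 2 / sig[0] ** 2
                                   + (u[j] - mu[1]) ** 2 / sig[1] ** 2))
                factor = A[i, j] if conv.edge_weighted else 1.0
                h[i] += factor * w * (X[j] @ conv.weights[k].data)
    return h / K


@pytest.mark.parametrize("edge_weighted", [True, False])
def test_gmm_matches_triple_loop_oracle(edge_weighted, rng):
    for K in (1, 2, 4):
        conv = GMMConv(4, 3, n_kernels=K, rng=rng, edge_weighted=edge_weighted)
        X = rng.standard_normal((5, 4))
        A = random_adjacency(rng, 5)
        out = conv(Tensor(X), Tensor(A)).data
        assert np.abs(out - gmm_loop_oracle(X, A, conv)).max() < 1e-6


def test_single_kernel_centered_on_coordinates_sums_neighbors(rng):
    """When every pseudo-coordinate equals the kernel mean, the kernel
    weight collapses to 1 and h_i = sum_{j in N(i)} x_j W."""
    n = 4
    A = np.ones((n, n))  # complete graph: all degrees equal
    conv = GMMConv(3, 2, n_kernels=1, rng=rng, edge_weighted=False)
    u = (n) ** -0.5  # every node has n neighbors (self included)
    conv.mu.data[:] = u
    X = rng.standard_normal((n, 3))
    out = conv(Tensor(X), Tensor(A)).data
    expected = np.ones((n, n)) @ X @ conv.weights[0].data
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_isolated_node_aggregates_only_itself(rng):
    """A self-loop-only node receives the kernel-weighted map of its own
    features, averaged over kernels."""
    A = np.eye(3)
    A[1, 2] = A[2, 1] = 0.5
    conv = GMMConv(3, 2, n_kernels=2, rng=rng)
    X = rng.standard_normal((3, 3))
    out = conv(Tensor(X), Tensor(A)).data
    u0 = 1.0  # deg(0) = 1
    acc = np.zeros(2)
    for k in range(2):
        mu, sig = conv.mu.data[k], np.exp(conv.log_sigma.data[k])
        w = np.exp(-0.5 * ((u0 - mu[0]) ** 2 / sig[0] ** 2
                           + (u0 - mu[1]) ** 2 / sig[1] ** 2))
        acc += w * (X[0] @ conv.weights[k].data)  # a_00 = 1
    np.testing.assert_allclose(out[0], acc / 2, atol=1e-10)


def test_nonpositive_sigma_impossible_by_construction(rng):
    conv = GMMConv(3, 2, n_kernels=2, rng=rng)
    assert (np.exp(conv.log_sigma.data) > 0).all()
    with pytest.raises(ValueError):
        GMMConv(3, 2, n_kernels=0, rng=rng)


# ----------------------------------------------------------------------
# Permutation equivariance and stacking
# ----------------------------------------------------------------------

@pytest.mark.parametrize("conv_name", ["gcn", "cheb", "gmm"])
def test_convolutions_are_permutation_equivariant(conv_name, rng):
    """conv(PX, PAP^T) == P conv(X, A) for random permutations P."""
    from graphmil.layers import apply_conv, make_conv

    conv = make_conv(conv_name, 4, 3, rng, n_kernels=2, cheb_order=3)
    X = rng.standard_normal((7, 4))
    A = random_adjacency(rng, 7)
    A_norm = normalize_adjacency(A)
    base = apply_conv(conv, Tensor(X), Tensor(A), Tensor(A_norm)).data
    for _ in range(5):
        p = rng.permutation(7)
        Ap = A[np.ix_(p, p)]
        out = apply_conv(conv, Tensor(X[p]), Tensor(Ap),
                         Tensor(normalize_adjacency(Ap))).data
        np.testing.assert_allclose(out, base[p], atol=1e-8)


def test_three_layer_stack_preserves_shape_and_finiteness(rng):
    stack = ConvStack([6, 8, 8, 5], conv="gmm", depth=3, n_kernels=2, rng=rng)
    X = rng.standard_normal((9, 6))
    A = random_adjacency(rng, 9)
    out = stack(Tensor(X), Tensor(A), Tensor(normalize_adjacency(A)))
    assert out.shape == (9, 5)
    assert np.isfinite(out.data).all()


# ----------------------------------------------------------------------
# Attention pooling
# ----------------------------------------------------------------------

def test_attention_scores_sum_to_one(rng):
    pool = AttentionPool(5, hidden=4, rng=rng)
    _, alpha = pool(Tensor(rng.standard_normal((7, 5))))
    assert alpha.data.sum() == pytest.approx(1.0)


def test_identical_embeddings_pool_uniformly(rng):
    h = rng.standard_normal(5)
    H = np.tile(h, (6, 1))
    pool = AttentionPool(5, hidden=4, rng=rng)
    g, alpha = pool(Tensor(H))
    np.testing.assert_allclose(alpha.data, 1 / 6)
    np.testing.assert_allclose(g.data.ravel(), h)


@pytest.mark.parametrize("gated", [False, True])
def test_pooling_is_permutation_invariant(gated, rng):
    pool = AttentionPool(5, hidden=4, gated=gated, rng=rng)
    H = rng.standard_normal((8, 5))
    g, alpha = pool(Tensor(H))
    p = rng.permutation(8)
    g_p, alpha_p = pool(Tensor(H[p]))
    np.testing.assert_allclose(g_p.data, g.data, atol=1e-12)
    np.testing.assert_allclose(alpha_p.data.ravel(), alpha.data.ravel()[p],
                               atol=1e-12)


# ----------------------------------------------------------------------
# Checkpoints
# ----------------------------------------------------------------------

def test_checkpoint_roundtrip_is_bit_exact(tmp_path, rng):
    state = {"W": rng.standard_normal((4, 3)), "b": rng.standard_normal(3)}
    path = tmp_path / "ckpt.npz"
    save_checkpoint(state, path, meta={"conv": "gmm"})
    loaded, meta = load_checkpoint(path)
    assert meta["conv"] == "gmm"
    assert meta["checkpoint_version"] == 1
    for k in state:
        np.testing.assert_array_equal(loaded[k], state[k])
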