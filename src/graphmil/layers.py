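"""Graph convolution operators and attention pooling.

Two convolution families are provided, matching the two encoders the model
ablates between:

* ``ChebConv`` — spectral filtering with Chebyshev polynomials of the
  scaled Laplacian L̂ = I − Ã (λ_max ≈ 2 absorbed into the scaling).
* ``GMMConv`` — spatial mixture-model convolution: neighbor messages are
  weighted by Gaussian kernels evaluated on per-edge pseudo-coordinates
  u_ij = (deg(i)^{-1/2}, deg(j)^{-1/2}); bags have no spatial layout, so
  degree-based coordinates are the natural choice.

``AttentionPool`` collapses node embeddings to a single bag vector with a
softmax attention over nodes (optionally gated), exposing the per-instance
scores used to rank significant patches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "normalize_adjacency",
    "normalize_adjacency_t",
    "GCNConv",
    "ChebConv",
    "GMMConv",
    "AttentionPool",
    "ConvStack",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization Ã = D^{-1/2} A D^{-1/2}.

    Requires a symmetric A with unit diagonal (self-loops already in
    place), which guarantees strictly positive degrees.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 1.0, atol=1e-10):
        raise ValueError("adjacency must carry unit self-loops")
    d_inv_sqrt = 1.0 / np.sqrt(A.sum(axis=1))
    return A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def normalize_adjacency_t(A: Tensor) -> Tensor:
    """Tensor version of symmetric normalization (gradients flow into A)."""
    d_inv_sqrt = A.sum(axis=1, keepdims=True) ** -0.5
    return A * d_inv_sqrt * d_inv_sqrt.T


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class GCNConv:
    """Plain propagation Ã X W (the printed two-layer-encoder operator)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = nn.Parameter(nn.glorot(rng, (d_in, d_out)))

    def parameters(self):
        return [self.W]

    def __call__(self, X, A_norm) -> Tensor:
        return _as_t(A_norm) @ (_as_t(X) @ self.W)


class ChebConv:
    """Chebyshev spectral filter of order K.

    out = Σ_{k=0}^{K-1} T_k(L̂) X W_k with L̂ = I − Ã and the recurrence
    T_0 = I, T_1 = L̂, T_k = 2 L̂ T_{k-1} − T_{k-2}.
    """

    def __init__(self, d_in: int, d_out: int, order: int,
                 rng: np.random.Generator):
        if order < 1:
            raise ValueError("Chebyshev order K must be >= 1")
        self.order = order
        self.weights = [nn.Parameter(nn.glorot(rng, (d_in, d_out)))
                        for _ in range(order)]

    def parameters(self):
        return list(self.weights)

    def __call__(self, X, A_norm) -> Tensor:
        X = _as_t(X)
        A_norm = _as_t(A_norm)
        n = A_norm.shape[0]
        L_hat = Tensor(np.eye(n)) - A_norm
        Tx_prev = X  # T_0(L̂) X = X
        out = Tx_prev @ self.weights[0]
        if self.order > 1:
            Tx = L_hat @ X
            out = out + Tx @ self.weights[1]
            for k in range(2, self.order):
                Tx, Tx_prev = 2.0 * (L_hat @ Tx) - Tx_prev, Tx
                out = out + Tx @ self.weights[k]
        return out


class GMMConv:
    """Gaussian-mixture-model convolution with K kernels (default 8).

    h_i = (1/K) Σ_k Σ_{j∈N(i)} a_ij · w_k(u_ij) · (x_j W_k)

    with w_k(u) = exp(−½ Σ_p (u_p − μ_{k,p})² / σ_{k,p}²) evaluated on the
    degree pseudo-coordinates, and N(i) the thresholded neighborhood
    including i itself.  Edge weights a_ij modulate messages by default
    (``edge_weighted=False`` reduces the factor to the binary mask).
    Kernel means and log-scales are learnable; pseudo-coordinates are
    treated as constants of the built graph.
    """

    def __init__(self, d_in: int, d_out: int, n_kernels: int = 8,
                 rng: np.random.Generator | None = None,
                 edge_weighted: bool = True, pseudo_dim: int = 2):
        if n_kernels < 1:
            raise ValueError("need at least one kernel")
        rng = rng or np.random.default_rng(0)
        self.n_kernels = n_kernels
        self.pseudo_dim = pseudo_dim
        self.edge_weighted = edge_weighted
        self.weights = [nn.Parameter(nn.glorot(rng, (d_in, d_out)))
                        for _ in range(n_kernels)]
        self.mu = nn.Parameter(rng.normal(0.0, 0.1, size=(n_kernels, pseudo_dim)) + 0.5)
        self.log_sigma = nn.Parameter(np.zeros((n_kernels, pseudo_dim)))

    def parameters(self):
        return [*self.weights, self.mu, self.log_sigma]

    @staticmethod
    def pseudo_coordinates(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """u_ij = (deg(i)^{-1/2}, deg(j)^{-1/2}), degrees = neighbor counts."""
        deg = (np.asarray(A) > 0).sum(axis=1).astype(np.float64)
        u = deg**-0.5
        return u[:, None], u[None, :]  # broadcastable column / row

    def kernel_weights(self, A: np.ndarray) -> list[Tensor]:
        """Per-kernel (n, n) Gaussian weights on the pseudo-coordinates."""
        u_col, u_row = self.pseudo_coordinates(A)
        out = []
        for k in range(self.n_kernels):
            mu_k = self.mu.data[k]
            expo = Tensor(np.zeros_like(np.broadcast_to(u_col + u_row, A.shape)))
            # p = 2 pseudo-dims: source-degree term then target-degree term
            for p, u_p in enumerate((u_col, u_row)):
                mu_kp = _slice_param(self.mu, k, p)
                sig_kp = _slice_param(self.log_sigma, k, p).exp()
                diff = Tensor(np.broadcast_to(u_p, A.shape).copy()) - mu_kp
                expo = expo + (diff * diff) / (sig_kp * sig_kp)
            out.append((-0.5 * expo).exp())
        return out

    def __call__(self, X, A, mask: np.ndarray | None = None) -> Tensor:
        X = _as_t(X)
        A = _as_t(A)
        if mask is None:
            mask = (A.data > 0).astype(np.float64)
        kernel_w = self.kernel_weights(mask)
        factor = A if self.edge_weighted else Tensor(mask)
        out = None
        for k in range(self.n_kernels):
            Mk = factor * kernel_w[k] * Tensor(mask)
            term = Mk @ (X @ self.weights[k])
            out = term if out is None else out + term
        return out * (1.0 / self.n_kernels)


def _slice_param(param: Tensor, k: int, p: int) -> Tensor:
    """Scalar view of param[k, p] that routes gradient back to the slot."""
    def bw(g):
        full = np.zeros_like(param.data)
        full[k, p] = g.sum()
        return (full,)

    return Tensor(param.data[k, p], parents=(param,), backward_fn=bw)


class AttentionPool:
    """Global attention pooling: α = softmax(wᵀ tanh(Vᵀh) [⊙ σ(Uᵀh)]).

    Returns the bag vector g = Σ_i α_i h_i and the per-node scores α
    (summing to 1), which double as instance-importance rankings.
    """

    def __init__(self, d_in: int, hidden: int = 64, gated: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.gated = gated
        self.V = nn.Parameter(nn.glorot(rng, (d_in, hidden)))
        self.w = nn.Parameter(nn.glorot(rng, (hidden, 1)))
        self.U = nn.Parameter(nn.glorot(rng, (d_in, hidden))) if gated else None

    def parameters(self):
        params = [self.V, self.w]
        if self.U is not None:
            params.append(self.U)
        return params

    def __call__(self, H) -> tuple[Tensor, Tensor]:
        H = _as_t(H)
        act = (H @ self.V).tanh()
        if self.gated:
            act = act * (H @ self.U).sigmoid()
        logits = act @ self.w  # (n, 1)
        alpha = nn.softmax(logits, axis=0)
        g = alpha.T @ H  # (1, d)
        return g, alpha


class ConvStack:
    """L stacked graph convolutions with ReLU between layers (default L=3)."""

    def __init__(self, dims: list[int], conv: str = "gmm", depth: int | None = None,
                 n_kernels: int = 8, cheb_order: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if depth is not None:
            if len(dims) != depth + 1:
                raise ValueError("dims must have depth+1 entries")
        self.conv_type = conv
        self.layers = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.layers.append(make_conv(conv, d_in, d_out, rng,
                                         n_kernels=n_kernels,
                                         cheb_order=cheb_order))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def __call__(self, X, A, A_norm, mask=None) -> Tensor:
        H = _as_t(X)
        for i, layer in enumerate(self.layers):
            H = apply_conv(layer, H, A, A_norm, mask)
            if i < len(self.layers) - 1:
                H = H.relu()
        return H


def make_conv(conv: str, d_in: int, d_out: int, rng: np.random.Generator,
              n_kernels: int = 8, cheb_order: int = 3):
    if conv == "gcn":
        return GCNConv(d_in, d_out, rng)
    if conv == "cheb":
        return ChebConv(d_in, d_out, cheb_order, rng)
    if conv == "gmm":
        return GMMConv(d_in, d_out, n_kernels, rng)
    raise ValueError(f"unknown convolution {conv!r}")


def apply_conv(layer, X, A, A_norm, mask=None) -> Tensor:
    """Dispatch on operator family: spectral layers consume Ã, GMMConv A."""
    if isinstance(layer, GMMConv):
        return layer(X, A, mask)
    return layer(X, A_norm)


# ----------------------------------------------------------------------
# Checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(state: dict, path: str | Path, meta: dict | None = None) -> None:
    """Versioned parameter container; reload is bit-exact (float64 npz)."""
    path = Path(path)
    flat = {k: np.asarray(v, dtype=np.float64) for k, v in state.items()}
    np.savez(path, **flat)
    meta = dict(meta or {})
    meta["checkpoint_version"] = CHECKPOINT_VERSION
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path) as z:
        state = {k: z[k].copy() for k in z.files}
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return state, meta
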