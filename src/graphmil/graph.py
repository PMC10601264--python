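"""Dense bag-graph construction with a learned adjacency.

Each bag becomes a dense graph: instances are nodes, and edges carry a
learned similarity.  The pipeline is

1. a permutation-invariant *context vector* c = φ(x_1 … x_n) pooled over
   the bag (deep-sets style),
2. *augmentation*: each instance is concatenated with c and passed through
   a small MLP, giving context-aware node features X*,
3. a *correlation layer*: a Gaussian kernel of the pairwise l2 distance
   between augmented features, hard-thresholded at τ, with self-loops
   fixed at 1.

The correlation layer's bandwidth is learnable, so the adjacency can be
trained jointly with the rest of the model (the default), or the graph can
be built once and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "context_pool",
    "build_adjacency",
    "DenseBagGraph",
    "GraphBuilder",
]


def context_pool(X: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Permutation-invariant pooling of instance features to one vector."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < 1 or X.size == 0:
        raise ValueError("context_pool: empty bag")
    if mode == "mean":
        return X.mean(axis=0)
    if mode == "max":
        return X.max(axis=0)
    if mode == "sum":
        return X.sum(axis=0)
    raise ValueError(f"unknown pooling mode {mode!r}")


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    s = (X * X).sum(axis=1)
    d2 = s[:, None] + s[None, :] - 2.0 * X @ X.T
    return np.maximum(d2, 0.0)


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median off-diagonal pairwise distance; 1.0 for single-instance bags."""
    n = X.shape[0]
    if n < 2:
        return 1.0
    d = np.sqrt(_pairwise_sq_dists(X))
    off = d[~np.eye(n, dtype=bool)]
    m = float(np.median(off))
    return m if m > 0 else 1.0


def build_adjacency(X_star: np.ndarray, tau: float | None = None,
                    sigma_a: float = 1.0) -> np.ndarray:
    """Correlation-layer adjacency: a_ij = exp(−‖x_i*−x_j*‖²/σ_a²)·[d_ij ≤ τ].

    Symmetric by construction, diagonal fixed at 1 (self-loops), entries
    beyond the distance threshold τ zeroed.  τ defaults to the median
    pairwise distance within the bag.
    """
    X_star = np.atleast_2d(np.asarray(X_star, dtype=np.float64))
    if not np.isfinite(X_star).all():
        raise ValueError("build_adjacency: non-finite features")
    if sigma_a <= 0:
        raise ValueError("sigma_a must be positive")
    n = X_star.shape[0]
    d2 = _pairwise_sq_dists(X_star)
    if tau is None:
        tau = median_pairwise_distance(X_star)
    A = np.exp(-d2 / sigma_a**2) * (np.sqrt(d2) <= tau)
    np.fill_diagonal(A, 1.0)
    return A


@dataclass
class DenseBagGraph:
    """Augmented node features X* plus the symmetric weighted adjacency A."""

    X_star: np.ndarray  # (n, d')
    A: np.ndarray  # (n, n), entries in [0, 1], diag = 1
    tau: float
    sigma_a: float

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def save(self, path: str | Path) -> None:
        """Upper-triangular adjacency + features; bit-exact round trip."""
        n = self.n_nodes
        iu = np.triu_indices(n)
        np.savez(path, X_star=self.X_star, A_upper=self.A[iu], n=n,
                 tau=self.tau, sigma_a=self.sigma_a)

    @staticmethod
    def load(path: str | Path) -> "DenseBagGraph":
        with np.load(path) as z:
            n = int(z["n"])
            A = np.zeros((n, n))
            iu = np.triu_indices(n)
            A[iu] = z["A_upper"]
            A = A + np.triu(A, 1).T
            return DenseBagGraph(X_star=z["X_star"], A=A, tau=float(z["tau"]),
                                 sigma_a=float(z["sigma_a"]))


class GraphBuilder:
    """Learnable bag-to-graph map: context pooling, MLP augmentation,
    correlation-layer adjacency.

    Parameters
    ----------
    feature_dim : input instance dimension d.
    mlp_hidden : hidden width of the augmentation MLP (default 123).
    aug_dim : output dimension d' of augmented features (default 123).
    pool_mode : context pooling operator φ, one of mean/max/sum.
    trainable_adjacency : if True (default) gradients flow through the
        MLP and the kernel bandwidth during end-to-end training; if False
        the graph is treated as a fixed pre-computed input.

    The kernel uses an effective bandwidth σ_eff = σ_a · m, where m is the
    (detached) median pairwise distance within the bag and σ_a = exp(log_sigma_a)
    is the learnable multiplier — this keeps the kernel scale-adaptive
    across bags of different spread.
    """

    def __init__(self, feature_dim: int, mlp_hidden: int = 123,
                 aug_dim: int = 123, pool_mode: str = "mean",
                 trainable_adjacency: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.aug_dim = aug_dim
        self.pool_mode = pool_mode
        self.trainable_adjacency = trainable_adjacency
        self.W1 = nn.Parameter(nn.glorot(rng, (2 * feature_dim, mlp_hidden)))
        self.b1 = nn.Parameter(np.zeros(mlp_hidden))
        self.W2 = nn.Parameter(nn.glorot(rng, (mlp_hidden, aug_dim)))
        self.b2 = nn.Parameter(np.zeros(aug_dim))
        self.log_sigma_a = nn.Parameter(0.0)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.log_sigma_a]

    def augment(self, X: np.ndarray) -> Tensor:
        """x_i* = MLP([x_i ‖ c]) with c = φ(X); returns an (n, d') tensor."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n, d = X.shape
        if d != self.feature_dim:
            raise ValueError(f"expected feature dim {self.feature_dim}, got {d}")
        c = context_pool(X, self.pool_mode)
        Xc = Tensor(np.concatenate([X, np.tile(c, (n, 1))], axis=1))
        H = (Xc @ self.W1 + self.b1).relu()
        return H @ self.W2 + self.b2

    def build(self, X: np.ndarray, tau: float | None = None) -> tuple[Tensor, Tensor, dict]:
        """Bag features → (X* tensor, adjacency tensor, aux info).

        aux carries the binary edge mask, τ, the effective bandwidth and
        node degrees — inputs the mixture-model convolution needs.
        """
        X_star = self.augment(X)
        if not self.trainable_adjacency:
            X_star = X_star.detach()
        n = X_star.shape[0]
        s = (X_star * X_star).sum(axis=1, keepdims=True)
        d2 = (s + s.T - 2.0 * (X_star @ X_star.T)).relu()
        dist = d2.data ** 0.5
        m = median_pairwise_distance(X_star.data)
        if tau is None:
            tau = m
        mask = (dist <= tau).astype(np.float64)
        np.fill_diagonal(mask, 0.0)  # diagonal handled separately (fixed 1)
        sigma_a = self.log_sigma_a.exp()
        sigma_eff_sq = sigma_a * sigma_a * (m * m)
        A_off = (-(d2 / sigma_eff_sq)).exp() * Tensor(mask)
        A = A_off + Tensor(np.eye(n))
        if not self.trainable_adjacency:
            A = A.detach()
        degrees = A.data.sum(axis=1)
        aux = {"mask": mask + np.eye(n), "tau": tau,
               "sigma_eff": float(np.sqrt(sigma_eff_sq.data)), "degrees": degrees}
        return X_star, A, aux

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict:
        return {"W1": self.W1.data, "b1": self.b1.data, "W2": self.W2.data,
                "b2": self.b2.data, "log_sigma_a": self.log_sigma_a.data}

    def load_state_dict(self, state: dict) -> None:
        for name, value in state.items():
            getattr(self, name).data = np.array(value, dtype=np.float64)
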