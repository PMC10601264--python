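"""Variational graph auto-encoder and the joint MIL objective.

The encoder is a two-layer graph convolution with a shared first layer:

    H        = ReLU(conv(X, A) · W_0)
    μ        = conv(H, A) · W_μ
    log σ    = conv(H, A) · W_σ

giving per-node diagonal Gaussians q(z_i | X, A) = N(μ_i, diag(σ_i²)).
Latent codes are sampled by reparameterization, and the inner-product
decoder reconstructs edges as p(A_ij = 1 | z_i, z_j) = logistic(z_iᵀ z_j).
Training minimizes the negative evidence lower bound — reweighted binary
cross-entropy on the (binarized) adjacency plus the closed-form KL to a
factorized standard-normal prior — optionally combined with a bag-level
classification cross-entropy into one joint objective.

The convolution operator is configurable (plain GCN as printed above,
ChebNet, or GMMConv); the full bag classifier defaults to GMMConv.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .graph import GraphBuilder
from .layers import (
    AttentionPool,
    GMMConv,
    apply_conv,
    make_conv,
    normalize_adjacency_t,
)

__all__ = [
    "EncoderParams",
    "Posterior",
    "ReconstructedAdjacency",
    "encode",
    "Encoder",
    "reparameterize",
    "decode",
    "kl_divergence",
    "elbo_loss",
    "mil_objective",
    "ModelConfig",
    "MILGNN",
    "fit_vgae",
]


@dataclass
class EncoderParams:
    """Weights of the printed two-layer GCN encoder (shared first layer)."""

    W_0: Tensor  # (d, h)
    W_mu: Tensor  # (h, D)
    W_sigma: Tensor  # (h, D)

    @staticmethod
    def init(d: int, hidden: int, latent_dim: int,
             rng: np.random.Generator) -> "EncoderParams":
        return EncoderParams(
            W_0=nn.Parameter(nn.glorot(rng, (d, hidden))),
            W_mu=nn.Parameter(nn.glorot(rng, (hidden, latent_dim))),
            W_sigma=nn.Parameter(nn.glorot(rng, (hidden, latent_dim))),
        )

    def parameters(self):
        return [self.W_0, self.W_mu, self.W_sigma]


@dataclass
class Posterior:
    """Per-node Gaussian q(z_i|X,A) = N(μ_i, diag(σ_i²))."""

    mu: Tensor  # (n, D)
    log_sigma: Tensor  # (n, D)


@dataclass
class ReconstructedAdjacency:
    """Edge probabilities σ(z_iᵀ z_j); logits kept for stable losses."""

    logits: Tensor  # (n, n)

    @property
    def probs(self) -> Tensor:
        return self.logits.sigmoid()

    @property
    def probs_np(self) -> np.ndarray:
        return self.probs.data


def encode(X, A_tilde, params: EncoderParams) -> Posterior:
    """Two-layer GCN encoder: μ = Ã ReLU(Ã X W_0) W_μ, log σ analogous.

    Identity-feature mode is simply X = I_n.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    A_tilde = A_tilde if isinstance(A_tilde, Tensor) else Tensor(A_tilde)
    H = (A_tilde @ (X @ params.W_0)).relu()
    mu = A_tilde @ (H @ params.W_mu)
    log_sigma = A_tilde @ (H @ params.W_sigma)
    return Posterior(mu=mu, log_sigma=log_sigma)


class Encoder:
    """Two-layer variational encoder with a configurable convolution.

    The first layer is shared between the μ and log σ heads; with
    ``conv="gcn"`` this reduces exactly to the printed formula.
    """

    def __init__(self, d_in: int, hidden: int, latent_dim: int,
                 conv: str = "gcn", n_kernels: int = 8, cheb_order: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv_type = conv
        self.shared = make_conv(conv, d_in, hidden, rng,
                                n_kernels=n_kernels, cheb_order=cheb_order)
        self.head_mu = make_conv(conv, hidden, latent_dim, rng,
                                 n_kernels=n_kernels, cheb_order=cheb_order)
        self.head_sigma = make_conv(conv, hidden, latent_dim, rng,
                                    n_kernels=n_kernels, cheb_order=cheb_order)

    def parameters(self):
        return (self.shared.parameters() + self.head_mu.parameters()
                + self.head_sigma.parameters())

    def __call__(self, X, A, A_norm, mask=None) -> Posterior:
        H = apply_conv(self.shared, X, A, A_norm, mask).relu()
        mu = apply_conv(self.head_mu, H, A, A_norm, mask)
        log_sigma = apply_conv(self.head_sigma, H, A, A_norm, mask)
        return Posterior(mu=mu, log_sigma=log_sigma)


def reparameterize(post: Posterior, seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Z = μ + σ ⊙ ε with ε ~ N(0, I); gradients flow through μ and log σ."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = Tensor(rng.standard_normal(post.mu.shape))
    return post.mu + post.log_sigma.exp() * eps


def decode(Z) -> ReconstructedAdjacency:
    """Inner-product decoder: p(A_ij = 1) = logistic(z_iᵀ z_j)."""
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    return ReconstructedAdjacency(logits=Z @ Z.T)


def kl_divergence(mu, log_sigma) -> Tensor:
    """Closed-form KL[q ‖ N(0, I)] summed over nodes and latent dims:

    −½ Σ_{i,d} (1 + 2 log σ − μ² − σ²)
    """
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    log_sigma = log_sigma if isinstance(log_sigma, Tensor) else Tensor(log_sigma)
    term = 1.0 + 2.0 * log_sigma - mu * mu - (2.0 * log_sigma).exp()
    return -0.5 * term.sum()


def elbo_loss(A_hat: ReconstructedAdjacency, A, post: Posterior,
              pos_weight: float | None = None) -> Tensor:
    """Negative ELBO: reweighted edge BCE plus per-node-averaged KL.

    The reconstruction target is the binarized adjacency (a_ij > 0 → 1;
    the decoder models Bernoulli edges while the built graph is weighted).
    ``pos_weight`` up-weights present edges; it defaults to the
    negative-to-positive edge ratio (n² − nnz)/nnz, the standard correction
    for sparse adjacencies.  Returned value is minimized.
    """
    A = A.data if isinstance(A, Tensor) else np.asarray(A, dtype=np.float64)
    B = (A > 0).astype(np.float64)
    n = B.shape[0]
    nnz = B.sum()
    if pos_weight is None:
        pos_weight = (n * n - nnz) / nnz if 0 < nnz < n * n else 1.0
    if pos_weight <= 0:
        raise ValueError("pos_weight must be positive")
    S = A_hat.logits
    # BCE with logits: pw·B·softplus(−s) + (1−B)·softplus(s)
    bce = Tensor(pos_weight * B) * (-S).softplus() + Tensor(1.0 - B) * S.softplus()
    recon = bce.mean()
    kl = kl_divergence(post.mu, post.log_sigma) * (1.0 / n)
    return recon + kl


def mil_objective(bag_logit, bag_label: int, neg_elbo,
                  lambda_vgae: float = 1.0) -> Tensor:
    """Joint loss: bag classification cross-entropy + λ · (negative ELBO)."""
    if lambda_vgae < 0:
        raise ValueError("lambda_vgae must be >= 0")
    s = bag_logit if isinstance(bag_logit, Tensor) else Tensor(bag_logit)
    y = float(bag_label)
    ce = (y * (-s).softplus() + (1.0 - y) * s.softplus()).sum()
    if lambda_vgae == 0 or neg_elbo is None:
        return ce
    neg_elbo = neg_elbo if isinstance(neg_elbo, Tensor) else Tensor(neg_elbo)
    return ce + lambda_vgae * neg_elbo


# ----------------------------------------------------------------------
# Full bag classifier
# ----------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture settings for the graph MIL classifier.

    ``depth`` counts graph convolutions end to end (default 3: one
    pre-encoder layer plus the two encoder layers).  ``pool_source``
    selects what attention pooling consumes — the posterior means (default,
    deterministic at inference), sampled latents, or the pre-encoder
    hidden features.
    """

    feature_dim: int = 16
    mlp_hidden: int = 123
    aug_dim: int = 123
    enc_hidden: int = 64
    latent_dim: int = 64
    conv: str = "gmm"  # gcn | cheb | gmm
    n_kernels: int = 8
    cheb_order: int = 3
    depth: int = 3
    attention_hidden: int = 64
    gated_attention: bool = False
    pool_source: str = "mu"  # mu | z | h
    pool_mode: str = "mean"
    trainable_adjacency: bool = True
    edge_weighted: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2 (the encoder itself is 2 layers)")
        if self.conv not in ("gcn", "cheb", "gmm"):
            raise ValueError(f"unknown conv {self.conv!r}")
        if self.pool_source not in ("mu", "z", "h"):
            raise ValueError(f"unknown pool_source {self.pool_source!r}")


@dataclass
class ForwardOutput:
    logit: Tensor  # (1, 1)
    attention: Tensor  # (n, 1)
    embedding: Tensor  # (1, D)
    posterior: Posterior
    neg_elbo: Tensor | None
    aux: dict


class MILGNN:
    """End-to-end bag classifier: learned graph → conv stack → VGAE →
    attention pooling → linear bag head.

    One forward pass consumes one bag's instance matrix; the training
    objective sums bag cross-entropy with the VGAE's negative ELBO.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.builder = GraphBuilder(
            c.feature_dim, mlp_hidden=c.mlp_hidden, aug_dim=c.aug_dim,
            pool_mode=c.pool_mode, trainable_adjacency=c.trainable_adjacency,
            rng=rng,
        )
        pre_dims = [c.aug_dim] + [c.enc_hidden] * (c.depth - 2)
        self.pre_layers = [
            make_conv(c.conv, d_in, d_out, rng, n_kernels=c.n_kernels,
                      cheb_order=c.cheb_order)
            for d_in, d_out in zip(pre_dims[:-1], pre_dims[1:])
        ]
        for layer in self.pre_layers:
            if isinstance(layer, GMMConv):
                layer.edge_weighted = c.edge_weighted
        enc_in = pre_dims[-1]
        self.encoder = Encoder(enc_in, c.enc_hidden, c.latent_dim, conv=c.conv,
                               n_kernels=c.n_kernels, cheb_order=c.cheb_order,
                               rng=rng)
        for head in (self.encoder.shared, self.encoder.head_mu,
                     self.encoder.head_sigma):
            if isinstance(head, GMMConv):
                head.edge_weighted = c.edge_weighted
        pool_dim = c.latent_dim if c.pool_source in ("mu", "z") else enc_in
        self.pool = AttentionPool(pool_dim, hidden=c.attention_hidden,
                                  gated=c.gated_attention, rng=rng)
        self.W_cls = nn.Parameter(nn.glorot(rng, (pool_dim, 1)))
        self.b_cls = nn.Parameter(np.zeros(1))
        self.trained_ = False

    def parameters(self) -> list[Tensor]:
        params = list(self.builder.parameters())
        for layer in self.pre_layers:
            params += layer.parameters()
        params += self.encoder.parameters()
        params += self.pool.parameters()
        params += [self.W_cls, self.b_cls]
        return params

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> ForwardOutput:
        c = self.config
        X_star, A, aux = self.builder.build(X)
        A_norm = normalize_adjacency_t(A)
        mask = aux["mask"]
        H = X_star
        for layer in self.pre_layers:
            H = apply_conv(layer, H, A, A_norm, mask).relu()
        post = self.encoder(H, A, A_norm, mask)
        neg_elbo = None
        Z = None
        if training:
            Z = reparameterize(post, rng=rng or np.random.default_rng(0))
            neg_elbo = elbo_loss(decode(Z), A, post)
        if c.pool_source == "mu":
            pooled_in = post.mu
        elif c.pool_source == "z":
            pooled_in = Z if Z is not None else post.mu
        else:
            pooled_in = H
        g, alpha = self.pool(pooled_in)
        logit = g @ self.W_cls + self.b_cls
        return ForwardOutput(logit=logit, attention=alpha, embedding=g,
                             posterior=post, neg_elbo=neg_elbo, aux=aux)

    def predict_score(self, X: np.ndarray) -> float:
        """Positive-class probability for one bag (deterministic)."""
        out = self.forward(X, training=False)
        return float(out.logit.sigmoid().data.ravel()[0])

    def attention_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).attention.data.ravel()

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            p.data = np.array(state[f"p{i}"], dtype=np.float64)


# ----------------------------------------------------------------------
# Standalone VGAE fitting (structure recovery, diagnostics)
# ----------------------------------------------------------------------

def fit_vgae(A: np.ndarray, latent_dim: int = 8, hidden: int = 16,
             epochs: int = 200, lr: float = 0.01, seed: int = 0,
             features: np.ndarray | None = None) -> tuple[EncoderParams, np.ndarray]:
    """Fit a plain-GCN VGAE to one graph; identity features by default.

    Full-batch Adam on the negative ELBO.  Returns the encoder parameters
    and the reconstructed edge-probability matrix from the posterior means.
    """
    from .layers import normalize_adjacency

    A = np.asarray(A, dtype=np.float64)
    n = A.shape[0]
    X = np.eye(n) if features is None else features
    A_tilde = Tensor(normalize_adjacency(A))
    rng = np.random.default_rng(seed)
    params = EncoderParams.init(X.shape[1], hidden, latent_dim, rng)
    opt = nn.Adam(params.parameters(), lr=lr)
    Xt = Tensor(X)
    for _ in range(epochs):
        opt.zero_grad()
        post = encode(Xt, A_tilde, params)
        Z = reparameterize(post, rng=rng)
        loss = elbo_loss(decode(Z), A, post)
        loss.backward()
        opt.step()
    post = encode(Xt, A_tilde, params)
    A_hat = decode(post.mu).probs_np
    return params, A_hat
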