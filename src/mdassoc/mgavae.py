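"""Variational graph autoencoder with a modified graph-convolution encoder.

Each entity graph (microbes or drugs) is encoded into per-node Gaussian
latents.  The first encoder layer is a *modified* graph convolution
(MGC): K propagation steps with a single collapsed weight matrix and no
inter-layer non-linearities,

    Y = row_softmax( S^K · X · M ),      S = D^{-1/2} A D^{-1/2},

which trades per-layer weights/activations for one cheap linear map.
Two heads share this hidden representation and produce the posterior
mean and log-variance through the normalized adjacency,

    mu = S · Y · W_mu,      log sigma^2 = S · Y · W_sigma,

latents are sampled with the reparameterization trick z = mu + sigma * eps,
and an inner-product decoder sigmoid(Z Z^T) reconstructs the adjacency.
Training minimizes the negative ELBO: positive-class-weighted binary
cross-entropy on the reconstruction plus the KL divergence to the
standard-normal prior (averaged per node).  Embeddings handed to the
downstream classifier are the posterior means (noise off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .similarity import FeatureGraph

__all__ = [
    "EncoderConfig",
    "EncoderWeights",
    "LatentEmbedding",
    "normalize_adjacency",
    "init_weights",
    "gcn_layer",
    "mgc_propagate",
    "encode",
    "reparameterize",
    "decode",
    "vgae_loss",
    "train",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of one entity-graph encoder.

    ``hidden_dim`` (d) and ``learning_rate`` default to the tuned values
    128 and 0.01; ``mgc_steps`` is the propagation depth K of the
    collapsed convolution.  ``use_reconstruction`` / ``use_kl`` are
    ablation switches for the two loss terms.
    """

    hidden_dim: int = 128
    latent_dim: int = 128
    learning_rate: float = 0.01
    epochs: int = 200
    mgc_steps: int = 2
    seed: int = 0
    leaky_relu_slope: float = 0.2
    use_reconstruction: bool = True
    use_kl: bool = True

    def __post_init__(self):
        if self.hidden_dim < 1 or self.latent_dim < 1:
            raise ValueError("hidden_dim and latent_dim must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mgc_steps < 1:
            raise ValueError("mgc_steps (K) must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class EncoderWeights:
    """Trainable matrices: collapsed MGC weight M, and the two head projections."""

    m_mgc: np.ndarray
    w_mu: np.ndarray
    w_sigma: np.ndarray


@dataclass
class LatentEmbedding:
    """Per-node posterior mean, log-variance and a sampled latent Z."""

    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        if not (self.mu.shape == self.log_var.shape == self.z.shape):
            raise ValueError("mu, log_var and z must share a shape")
        if not np.isfinite(self.z).all():
            raise ValueError("latent z contains non-finite values")


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} A D^{-1/2} (no self-loops added).

    Zero-degree nodes are given degree 1 so the normalization is defined;
    their rows stay zero.
    """
    a = np.asarray(adjacency, dtype=np.float64)
    if np.abs(a - a.T).max() > 1e-8:
        raise ValueError("adjacency must be symmetric")
    deg = a.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_weights(n_features: int, config: EncoderConfig) -> EncoderWeights:
    """Seeded Glorot-uniform initialization of all trainable matrices."""
    rng = np.random.default_rng(config.seed)
    return EncoderWeights(
        m_mgc=_glorot(rng, n_features, config.hidden_dim),
        w_mu=_glorot(rng, config.hidden_dim, config.latent_dim),
        w_sigma=_glorot(rng, config.hidden_dim, config.latent_dim),
    )


# ---------------------------------------------------------------------------
# forward pieces (numpy in, numpy out; training re-builds them on Tensors)


def gcn_layer(features, a_norm, w0, slope: float = 0.2) -> np.ndarray:
    """Plain graph-convolution layer LeakyReLU(S X W0) (reference layer)."""
    features, a_norm, w0 = (np.asarray(x, dtype=np.float64) for x in (features, a_norm, w0))
    pre = a_norm @ features @ w0
    return np.where(pre > 0, pre, slope * pre)


def _propagate(features: np.ndarray, s: np.ndarray, steps: int) -> np.ndarray:
    out = np.asarray(features, dtype=np.float64)
    for _ in range(steps):
        out = s @ out
    return out


def mgc_propagate(features, s, m, steps: int) -> np.ndarray:
    """Modified graph convolution: row_softmax(S^K X M)."""
    if steps < 1:
        raise ValueError("MGC needs at least one propagation step")
    pre = _propagate(features, np.asarray(s, dtype=np.float64), steps) @ np.asarray(m)
    shifted = pre - pre.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def encode(features, a_norm, weights: EncoderWeights, config: EncoderConfig) -> LatentEmbedding:
    """Deterministic encode: MGC hidden layer, then mean/log-variance heads.

    Inference-mode: z is set to mu (no sampling noise).
    """
    hidden = mgc_propagate(features, a_norm, weights.m_mgc, config.mgc_steps)
    sh = np.asarray(a_norm) @ hidden
    mu = sh @ weights.w_mu
    log_var = sh @ weights.w_sigma
    if not (np.isfinite(mu).all() and np.isfinite(log_var).all()):
        raise FloatingPointError("non-finite values in encoder heads")
    return LatentEmbedding(mu=mu, log_var=log_var, z=mu.copy())


def reparameterize(mu: np.ndarray, log_var: np.ndarray, noise) -> np.ndarray:
    """z = mu + sigma * eps with sigma = exp(log_var / 2).

    ``noise`` is either an eps array of matching shape or a Generator to
    draw standard-normal eps from.
    """
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    if isinstance(noise, np.random.Generator):
        eps = noise.standard_normal(mu.shape)
    else:
        eps = np.asarray(noise, dtype=np.float64)
        if eps.shape != mu.shape:
            raise ValueError("noise shape must match mu")
    return mu + np.exp(0.5 * log_var) * eps


def decode(z: np.ndarray) -> np.ndarray:
    """Inner-product decoder sigmoid(Z Z^T); symmetric, entries in (0,1)."""
    z = np.asarray(z, dtype=np.float64)
    logits = z @ z.T
    return 1.0 / (1.0 + np.exp(-logits))


def vgae_loss(
    reconstructed: np.ndarray,
    adjacency: np.ndarray,
    mu: np.ndarray,
    log_var: np.ndarray,
    *,
    pos_weight: float | None = None,
) -> float:
    """Negative ELBO: weighted BCE(P, A) + KL(N(mu, sigma^2) || N(0, I)) / n.

    Probabilities are clamped away from exact 0/1 before the logs.  With
    ``pos_weight=None`` the weight is the negative/positive entry ratio
    of ``adjacency`` (1.0 if the adjacency has no positives).
    """
    p = np.clip(np.asarray(reconstructed, dtype=np.float64), 1e-12, 1 - 1e-12)
    a = np.asarray(adjacency, dtype=np.float64)
    if pos_weight is None:
        pos_weight = _default_pos_weight(a)
    bce = -(pos_weight * a * np.log(p) + (1 - a) * np.log(1 - p)).mean()
    mu = np.asarray(mu, dtype=np.float64)
    log_var = np.asarray(log_var, dtype=np.float64)
    kl = -0.5 * np.sum(1 + log_var - mu**2 - np.exp(log_var)) / mu.shape[0]
    return float(bce + kl)


def _default_pos_weight(a: np.ndarray) -> float:
    n_pos = a.sum()
    if n_pos == 0 or n_pos == a.size:
        return 1.0
    return float((a.size - n_pos) / n_pos)


# ---------------------------------------------------------------------------
# training


def _forward_tensors(skx, s, params, adjacency, config, eps, pos_weight):
    """Build the training loss graph; returns (loss, mu, log_var)."""
    hidden = ad.softmax_rows(ad.matmul(skx, params["m_mgc"]))
    sh = ad.matmul(s, hidden)
    mu = ad.matmul(sh, params["w_mu"])
    log_var = ad.matmul(sh, params["w_sigma"])
    sigma = ad.exp(ad.scale(log_var, 0.5))
    z = ad.add(mu, ad.mul(sigma, ad.constant(eps)))
    logits = ad.matmul(z, Tensor_T(z))
    n = adjacency.shape[0]
    terms = []
    if config.use_reconstruction:
        terms.append(ad.weighted_bce_with_logits(logits, adjacency, pos_weight))
    if config.use_kl:
        terms.append(ad.scale(ad.gaussian_kl(mu, log_var), 1.0 / n))
    loss = terms[0] if terms else None
    for t in terms[1:]:
        loss = ad.add(loss, t)
    return loss, mu, log_var


def Tensor_T(x: ad.Tensor) -> ad.Tensor:
    """Transpose op for the autodiff graph."""

    def backward(g):
        x.grad += g.T

    return ad.Tensor(x.value.T, parents=(x,), backward=backward)


def _monitor_loss(graph, s, weights, config, eps, pos_weight) -> float:
    """Loss at the current weights under a FIXED noise draw.

    The per-epoch trace uses common random numbers: with the noise held
    fixed, successive values differ only through the weights, so the
    trace reflects optimization progress instead of sampling luck.
    """
    emb = encode(graph.features, s, weights, config)
    z = reparameterize(emb.mu, emb.log_var, eps)
    total = 0.0
    if config.use_reconstruction:
        p = np.clip(decode(z), 1e-12, 1 - 1e-12)
        a = graph.adjacency
        total -= (pos_weight * a * np.log(p) + (1 - a) * np.log(1 - p)).mean()
    if config.use_kl:
        total += (
            -0.5
            * np.sum(1 + emb.log_var - emb.mu**2 - np.exp(emb.log_var))
            / graph.n_nodes
        )
    return float(total)


def train(graph: FeatureGraph, config: EncoderConfig):
    """Fit the VGAE on one entity graph by Adam on the negative ELBO.

    Returns ``(weights, embedding, losses)`` where the embedding carries
    z = mu (inference mode) and ``losses`` is the per-epoch monitoring
    trace (fixed noise draw; gradient steps resample fresh noise every
    epoch).  With both loss terms disabled (ablation "blank" mode) or
    epochs=0 the initialized weights are returned untrained.
    """
    s = normalize_adjacency(graph.adjacency)
    skx = _propagate(graph.features, s, config.mgc_steps)
    weights = init_weights(graph.features.shape[1], config)
    losses: list[float] = []
    trainable = config.epochs > 0 and (config.use_reconstruction or config.use_kl)
    if trainable:
        rng = np.random.default_rng(config.seed + 1)
        eps_monitor = rng.standard_normal((graph.n_nodes, config.latent_dim))
        params = {
            "m_mgc": ad.parameter(weights.m_mgc, "M"),
            "w_mu": ad.parameter(weights.w_mu, "W_mu"),
            "w_sigma": ad.parameter(weights.w_sigma, "W_sigma"),
        }
        pos_weight = _default_pos_weight(graph.adjacency)
        opt = ad.Adam(params.values(), lr=config.learning_rate)
        skx_t = ad.constant(skx, "S^K X")
        s_t = ad.constant(s, "S")
        for _ in range(config.epochs):
            eps = rng.standard_normal((graph.n_nodes, config.latent_dim))
            loss, _, _ = _forward_tensors(
                skx_t, s_t, params, graph.adjacency, config, eps, pos_weight
            )
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    "VGAE training diverged (loss is not finite); try a lower learning rate"
                )
            loss.backward()
            opt.step()
            current = EncoderWeights(
                m_mgc=params["m_mgc"].value,
                w_mu=params["w_mu"].value,
                w_sigma=params["w_sigma"].value,
            )
            losses.append(_monitor_loss(graph, s, current, config, eps_monitor, pos_weight))
        weights = current
    embedding = encode(graph.features, s, weights, config)
    return weights, embedding, losses
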