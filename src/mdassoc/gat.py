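"""Multi-head graph attention refinement on the bipartite association graph.

The VGAE embeds each entity graph separately; this stage stacks the two
embeddings, Z = [Z_m; Z_d], on the bipartite graph whose adjacency is
the block matrix [[0, A], [A^T, 0]] (A = training associations), and
refines them with multi-head graph attention:

    e_ij = LeakyReLU([Z'_i || Z'_j] · W_e),   Z' = Z W_z
    a_ij = softmax_j over the first-order neighborhood N_i
    out_i = LeakyReLU( sum_{k in N_i} a_ik Z'_k )

Per-head outputs are concatenated (width = heads x out_dim).  The heads
are trained to reconstruct the training association matrix from the
microbe-drug inner products of the refined embeddings; held-out test
edges are never placed in the graph, so no test label reaches the
attention weights.  Nodes with no training association keep their VGAE
embedding unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .graph_data import AssociationMatrix
from .mgavae import _default_pos_weight

__all__ = [
    "AttentionConfig",
    "AttentionWeights",
    "build_bipartite_adjacency",
    "attention_coefficients",
    "gat_layer",
    "multi_head",
    "refine_embeddings",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Multi-head attention hyperparameters.

    Defaults keep the refined width equal to the VGAE latent width:
    4 heads x 32 dims = 128.
    """

    heads: int = 4
    out_dim: int = 32
    leaky_relu_slope: float = 0.2
    seed: int = 0
    epochs: int = 100
    learning_rate: float = 0.01

    def __post_init__(self):
        if self.heads < 1 or self.out_dim < 1:
            raise ValueError("heads and out_dim must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class AttentionWeights:
    """Per-head feature transforms W_z and attention vectors W_e.

    Each attention vector is stored in its two halves: ``we_src`` acts
    on the aggregating node's transformed feature, ``we_dst`` on the
    neighbor's, so [Z'_i || Z'_j] · W_e = Z'_i·we_src + Z'_j·we_dst.
    """

    wz: list[np.ndarray]
    we_src: list[np.ndarray]
    we_dst: list[np.ndarray]

    def __post_init__(self):
        if not (len(self.wz) == len(self.we_src) == len(self.we_dst)):
            raise ValueError("one transform and one attention vector required per head")

    @property
    def heads(self) -> int:
        return len(self.wz)


def build_bipartite_adjacency(associations: AssociationMatrix) -> np.ndarray:
    """Block adjacency [[0, A], [A^T, 0]]; microbes first, then drugs."""
    a = associations.values.astype(np.float64)
    i, j = a.shape
    m = np.zeros((i + j, i + j))
    m[:i, i:] = a
    m[i:, :i] = a.T
    return m


def init_attention_weights(in_dim: int, config: AttentionConfig) -> AttentionWeights:
    rng = np.random.default_rng(config.seed)
    limit_z = np.sqrt(6.0 / (in_dim + config.out_dim))
    limit_e = np.sqrt(6.0 / (config.out_dim + 1))
    wz, we_src, we_dst = [], [], []
    for _ in range(config.heads):
        wz.append(rng.uniform(-limit_z, limit_z, size=(in_dim, config.out_dim)))
        we_src.append(rng.uniform(-limit_e, limit_e, size=(config.out_dim, 1)))
        we_dst.append(rng.uniform(-limit_e, limit_e, size=(config.out_dim, 1)))
    return AttentionWeights(wz, we_src, we_dst)


def attention_coefficients(
    z_prime: np.ndarray,
    adjacency: np.ndarray,
    we_src: np.ndarray,
    we_dst: np.ndarray,
    slope: float = 0.2,
) -> np.ndarray:
    """Softmax-normalized attention over each node's first-order neighborhood.

    Returns a dense matrix whose row i holds a_ij for j in N_i and 0
    elsewhere; rows of isolated nodes are all-zero.
    """
    z_prime = np.asarray(z_prime, dtype=np.float64)
    mask = np.asarray(adjacency) > 0
    u = (z_prime @ np.asarray(we_src)).reshape(-1)
    v = (z_prime @ np.asarray(we_dst)).reshape(-1)
    e = u[:, None] + v[None, :]
    e = np.where(e > 0, e, slope * e)
    neg = np.where(mask, e, -np.inf)
    row_max = np.max(neg, axis=1, keepdims=True)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    ex = np.where(mask, np.exp(neg - row_max), 0.0)
    denom = ex.sum(axis=1, keepdims=True)
    return ex / np.where(denom > 0, denom, 1.0)


def gat_layer(
    features: np.ndarray,
    adjacency: np.ndarray,
    weights: AttentionWeights,
    config: AttentionConfig,
    head: int,
) -> np.ndarray:
    """One attention head: aggregate transformed neighbor features.

    Isolated nodes pass their transformed self-feature Z'_i through
    unchanged (no activation, no attention).
    """
    z_prime = np.asarray(features, dtype=np.float64) @ weights.wz[head]
    coeff = attention_coefficients(
        z_prime, adjacency, weights.we_src[head], weights.we_dst[head], config.leaky_relu_slope
    )
    agg = coeff @ z_prime
    out = np.where(agg > 0, agg, config.leaky_relu_slope * agg)
    isolated = np.asarray(adjacency).sum(axis=1) == 0
    out[isolated] = z_prime[isolated]
    return out


def multi_head(
    features: np.ndarray,
    adjacency: np.ndarray,
    weights: AttentionWeights,
    config: AttentionConfig,
) -> np.ndarray:
    """Concatenate all head outputs: shape (N, heads * out_dim)."""
    return np.hstack(
        [gat_layer(features, adjacency, weights, config, h) for h in range(weights.heads)]
    )


# ---------------------------------------------------------------------------
# trained refinement


def _head_tensors(z, mask, isolated, wz, we_src, we_dst, slope):
    z_prime = ad.matmul(z, wz)
    u = ad.matmul(z_prime, we_src)  # (N,1)
    v = ad.matmul(z_prime, we_dst)
    e = ad.leaky_relu(ad.add(u, Tensor_T(v)), slope)
    coeff = ad.masked_softmax_rows(e, mask)
    agg = ad.leaky_relu(ad.matmul(coeff, z_prime), slope)
    # isolated nodes keep their transformed self-feature
    return ad.row_mix(~isolated, agg, z_prime)


def Tensor_T(x: ad.Tensor) -> ad.Tensor:
    def backward(g):
        x.grad += g.T

    return ad.Tensor(x.value.T, parents=(x,), backward=backward)


def refine_embeddings(
    zm: np.ndarray,
    zd: np.ndarray,
    associations: AssociationMatrix,
    config: AttentionConfig,
):
    """Train the attention heads on bipartite reconstruction; return refined Zm, Zd.

    ``associations`` must hold training-fold labels only.  The loss is
    positive-weighted BCE between sigmoid(Zm_ref · Zd_ref^T) and the
    training matrix.  After training, nodes without any training
    association are given back their input embedding (if the widths
    match) rather than an attention output computed from an empty
    neighborhood.
    """
    zm = np.asarray(zm, dtype=np.float64)
    zd = np.asarray(zd, dtype=np.float64)
    if associations.n_associations == 0:
        raise ValueError("refinement needs at least one training association")
    if zm.shape[1] != zd.shape[1]:
        raise ValueError("microbe and drug embeddings must share a width")
    n_m = zm.shape[0]
    adjacency = build_bipartite_adjacency(associations)
    mask = adjacency > 0
    isolated = adjacency.sum(axis=1) == 0
    z = np.vstack([zm, zd])
    weights = init_attention_weights(z.shape[1], config)

    params: list[ad.Tensor] = []
    wz_t = [ad.parameter(w) for w in weights.wz]
    ws_t = [ad.parameter(w) for w in weights.we_src]
    wd_t = [ad.parameter(w) for w in weights.we_dst]
    params = [*wz_t, *ws_t, *wd_t]
    z_const = ad.constant(z)
    a_train = associations.values.astype(np.float64)
    pos_weight = _default_pos_weight(a_train)
    opt = ad.Adam(params, lr=config.learning_rate)
    losses: list[float] = []
    for _ in range(config.epochs):
        heads = [
            _head_tensors(z_const, mask, isolated, wz_t[h], ws_t[h], wd_t[h], config.leaky_relu_slope)
            for h in range(config.heads)
        ]
        z_ref = heads[0] if len(heads) == 1 else _hstack(heads)
        zm_ref = _take_rows(z_ref, slice(0, n_m))
        zd_ref = _take_rows(z_ref, slice(n_m, None))
        logits = ad.matmul(zm_ref, Tensor_T(zd_ref))
        loss = ad.weighted_bce_with_logits(logits, a_train, pos_weight)
        if not np.isfinite(loss.value):
            raise FloatingPointError("attention refinement diverged (loss not finite)")
        loss.backward()
        opt.step()
        losses.append(float(loss.value))

    final = AttentionWeights(
        [w.value for w in wz_t], [w.value for w in ws_t], [w.value for w in wd_t]
    )
    refined = multi_head(z, adjacency, final, config)
    if refined.shape[1] == z.shape[1]:
        refined[isolated] = z[isolated]
    return refined[:n_m], refined[n_m:], losses


def _hstack(tensors):
    widths = [t.value.shape[1] for t in tensors]
    offsets = np.cumsum([0, *widths])
    value = np.hstack([t.value for t in tensors])

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t.grad += g[:, lo:hi]

    return ad.Tensor(value, parents=tuple(tensors), backward=backward)


def _take_rows(x: ad.Tensor, rows: slice) -> ad.Tensor:
    def backward(g):
        x.grad[rows] += g

    return ad.Tensor(x.value[rows], parents=(x,), backward=backward)
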