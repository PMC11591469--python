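"""Graph Convolutional Attention Network (GCAN) encoder.

One or more GCN layers pre-encode the node features of the
heterogeneous graph, giving the attention stack a structurally informed
initialisation.  Each attention layer then scores every neighbour pair
with a shared linear transform and a learnable attention vector
(LeakyReLU on the concatenated pair, softmax over the neighbourhood),
aggregates the transformed neighbour features with those weights, and
concatenates Q heads.  Layer outputs are combined through a learnable
skip connection: the last layer's output plus a weighted sum of the
earlier layers.

The module exposes the per-operation math as plain numpy functions
(useful for inspection and as building blocks for naive reference
evaluations) and a vectorised tape-based ``encode_gcan`` used for
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, constant, parameter
from .data import HeterogeneousGraph

__all__ = [
    "GCANConfig",
    "GCANState",
    "init_gcan_state",
    "gcn_layer",
    "attention_coefficients",
    "attention_weights",
    "attention_aggregate",
    "multi_head_layer",
    "skip_fusion",
    "encode_gcan",
]


@dataclass
class GCANConfig:
    """Hyperparameters of the attention encoder.

    ``dim`` is the embedding width D; each of the ``heads`` attention
    heads works at width D / heads so concatenation restores D.
    ``use_gcn_pre=False`` bypasses the GCN pre-encoding, giving the
    plain graph-attention variant used in ablations.
    """

    gcn_layers: int = 1
    att_layers: int = 2
    heads: int = 4
    dim: int = 512
    leaky_relu_slope: float = 0.2
    dropout: float = 0.5
    use_gcn_pre: bool = True

    def __post_init__(self):
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.att_layers < 1 or self.heads < 1 or self.gcn_layers < 1:
            raise ValueError("layer and head counts must be >= 1")


@dataclass
class GCANState:
    """Learnable parameters: GCN weights, per-head attention transforms
    and vectors per layer, and the skip-fusion scalars."""

    gcn_weights: list[Tensor]
    head_transforms: list[list[Tensor]]  # [layer][head] -> W_h
    attention_vectors: list[list[Tensor]]  # [layer][head] -> a
    skip_weights: Tensor  # length att_layers - 1

    def named_params(self, prefix: str = "gcan"):
        for l, w in enumerate(self.gcn_weights):
            yield f"{prefix}.gcn.{l}.W", w
        for l in range(len(self.head_transforms)):
            for q in range(len(self.head_transforms[l])):
                yield f"{prefix}.att.{l}.{q}.W_h", self.head_transforms[l][q]
                yield f"{prefix}.att.{l}.{q}.a", self.attention_vectors[l][q]
        yield f"{prefix}.skip_alpha", self.skip_weights


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_gcan_state(config: GCANConfig, in_dim: int, rng: np.random.Generator) -> GCANState:
    """Seeded Xavier-uniform initialisation; skip scalars start at 1/(L-1)."""
    d = config.dim
    gcn_weights = []
    cur = in_dim
    if config.use_gcn_pre:
        for l in range(config.gcn_layers):
            gcn_weights.append(parameter(_xavier(rng, cur, d), name=f"gcn{l}"))
            cur = d
    head_dim = d // config.heads
    transforms, vectors = [], []
    for l in range(config.att_layers):
        tl, vl = [], []
        for q in range(config.heads):
            tl.append(parameter(_xavier(rng, cur, head_dim)))
            vl.append(parameter(_xavier(rng, 2 * head_dim, 1)[:, 0]))
        transforms.append(tl)
        vectors.append(vl)
        cur = d
    alpha0 = 1.0 / max(config.att_layers - 1, 1)
    skip = parameter(np.full(max(config.att_layers - 1, 0), alpha0), name="skip")
    return GCANState(gcn_weights, transforms, vectors, skip)


# ---------------------------------------------------------------------------
# Per-operation math (plain numpy)


def gcn_layer(features: np.ndarray, neighbors: list[np.ndarray], weight: np.ndarray) -> np.ndarray:
    """One GCN propagation ``h_i' = ReLU(sum_{j in N(i)+{i}} W h_j / sqrt(d_i d_j))``
    with self-loop-inclusive degrees ``d = |N(.)| + 1``."""
    n = features.shape[0]
    deg = np.array([len(nb) + 1 for nb in neighbors], dtype=np.float64)
    transformed = features @ weight
    out = np.zeros((n, weight.shape[1]))
    for i in range(n):
        idx = np.concatenate([np.asarray(neighbors[i], dtype=np.intp), [i]])
        if idx.max() >= n or idx.min() < 0:
            raise IndexError("neighbor index out of range")
        coeff = 1.0 / np.sqrt(deg[i] * deg[idx])
        out[i] = coeff @ transformed[idx]
    return np.maximum(out, 0.0)


def attention_coefficients(
    h_i: np.ndarray, h_j: np.ndarray, a: np.ndarray, w_h: np.ndarray, slope: float = 0.2
) -> float:
    """Unnormalised attention score LeakyReLU(a^T [W_h h_i || W_h h_j]).

    Asymmetric in (i, j) by construction: the concatenation order matters.
    """
    pair = np.concatenate([h_i @ w_h, h_j @ w_h])
    if pair.shape[0] != a.shape[0]:
        raise ValueError("attention vector length must be twice the head width")
    e = float(a @ pair)
    return e if e > 0 else slope * e


def attention_weights(coeffs: np.ndarray) -> np.ndarray:
    """Softmax-normalise the coefficients of one neighbourhood."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.size == 0:
        raise ValueError("empty neighborhood: caller must supply a fallback self-edge")
    e = np.exp(coeffs - coeffs.max())
    return e / e.sum()


def attention_aggregate(
    weights: np.ndarray, neighbor_feats: np.ndarray, w_h: np.ndarray
) -> np.ndarray:
    """ReLU of the attention-weighted sum of transformed neighbour features."""
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must sum to 1")
    return np.maximum(weights @ (neighbor_feats @ w_h), 0.0)


def multi_head_layer(
    features: np.ndarray,
    neighbors: list[np.ndarray],
    head_transforms: list[np.ndarray],
    head_vectors: list[np.ndarray],
    slope: float = 0.2,
) -> np.ndarray:
    """One attention layer: per-head aggregation, heads concatenated."""
    widths = {w.shape[1] for w in head_transforms}
    if len(widths) != 1:
        raise ValueError("all heads must share the same width")
    n = features.shape[0]
    outs = []
    for w_h, a in zip(head_transforms, head_vectors):
        z = np.zeros((n, w_h.shape[1]))
        for i in range(n):
            idx = np.asarray(neighbors[i], dtype=np.intp)
            coeffs = np.array(
                [attention_coefficients(features[i], features[j], a, w_h, slope) for j in idx]
            )
            alpha = attention_weights(coeffs)
            z[i] = attention_aggregate(alpha, features[idx], w_h)
        outs.append(z)
    return np.concatenate(outs, axis=1)


def skip_fusion(layer_outputs: list[np.ndarray], skip_weights: np.ndarray) -> np.ndarray:
    """H = h^(L) + sum_{l<L} alpha_l h^(l)."""
    if len(skip_weights) != len(layer_outputs) - 1:
        raise ValueError("need one skip weight per non-final layer")
    out = layer_outputs[-1].copy()
    for alpha, h in zip(skip_weights, layer_outputs[:-1]):
        out = out + alpha * h
    return out


# ---------------------------------------------------------------------------
# Vectorised tape-based encoder


def _neighbor_mask(neighbors: list[np.ndarray], n: int) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    for i, idx in enumerate(neighbors):
        mask[i, idx] = True
    return mask


def _gcn_coefficients(neighbors: list[np.ndarray], n: int) -> np.ndarray:
    deg = np.array([len(nb) + 1 for nb in neighbors], dtype=np.float64)
    c = np.zeros((n, n))
    for i, idx in enumerate(neighbors):
        c[i, idx] = 1.0 / np.sqrt(deg[i] * deg[idx])
        c[i, i] = 1.0 / deg[i]
    return c


def encode_gcan(
    graph: HeterogeneousGraph,
    config: GCANConfig,
    state: GCANState,
    rng: np.random.Generator | None = None,
    training: bool = False,
    features: Tensor | None = None,
) -> Tensor:
    """Full GCAN forward pass producing the (M+N) x D embedding H_AG."""
    n = graph.n_nodes
    x = features if features is not None else constant(graph.features)
    mask = _neighbor_mask(graph.neighbor_lists, n)
    if config.use_gcn_pre:
        coeff = constant(_gcn_coefficients(graph.neighbor_lists, n))
        for w in state.gcn_weights:
            x = (coeff @ (x @ w)).relu()
    layer_outputs: list[Tensor] = []
    for l in range(config.att_layers):
        x = x.dropout(config.dropout, rng, training)
        heads = []
        for q in range(config.heads):
            w_h = state.head_transforms[l][q]
            a = state.attention_vectors[l][q]
            f = x @ w_h  # (n, head_dim)
            s_src = _split_matvec(f, a, 0)
            s_dst = _split_matvec(f, a, 1)
            logits = (s_src + s_dst.T).leaky_relu(config.leaky_relu_slope)
            alpha = logits.softmax_rows(mask=mask)
            row_sums = alpha.value.sum(axis=1)
            assert np.allclose(row_sums, 1.0, atol=1e-6), "attention rows must sum to 1"
            heads.append((alpha @ f).relu())
        out = heads[0]
        for h in heads[1:]:
            out = out.concat(h, axis=1)
        layer_outputs.append(out)
        x = out
    h_ag = layer_outputs[-1]
    for l in range(config.att_layers - 1):
        alpha_l = state.skip_weights.gather_rows(np.array([l]))
        h_ag = h_ag + alpha_l * layer_outputs[l]
    return h_ag


def _split_matvec(f: Tensor, a: Tensor, half: int) -> Tensor:
    """f @ a[half]: column vector (n, 1) from one half of the attention vector."""
    dh = f.shape[1]
    idx = np.arange(half * dh, (half + 1) * dh)
    a_half = a.gather_rows(idx)
    # (n, dh) @ (dh,) -> promote to column
    out = f @ _as_column(a_half)
    return out


def _as_column(v: Tensor) -> Tensor:
    out = Tensor(v.value.reshape(-1, 1), (v,))

    def bwd(g):
        if v.requires_grad:
            v._accum(g.reshape(v.value.shape))

    out._backward = bwd
    return out
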