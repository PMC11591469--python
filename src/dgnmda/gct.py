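"""Graph Convolutional Transformer (GCT) encoder.

A stack of E graph-convolution layers over the symmetrically normalised
heterogeneous adjacency encodes local structure; a multi-head
self-attention layer then models global dependencies.  To keep the
attention distance-aware, every logit (i, j) receives a non-positive
Gaussian bias ``-|omega * k_ij^2 + b|`` in the squared hop distance
k_ij, with omega and b learnable scalars shared across heads: omega
scales how fast attention decays with distance and a negative b
penalises self-attention.  Residual connections, layer normalisation
and a two-layer feed-forward network complete the block.

Ablation switches: ``use_attention=False`` keeps only the convolution
stack; ``use_graph_conv=False`` together with ``use_gaussian_bias=False``
yields a conventional transformer on linearly projected node features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, constant, parameter
from .data import HeterogeneousGraph

__all__ = [
    "GCTConfig",
    "GCTState",
    "init_gct_state",
    "graph_conv_stack",
    "gaussian_bias",
    "biased_attention_head",
    "concat_heads",
    "transformer_block",
    "encode_gct",
]

_LN_EPS = 1e-5


@dataclass
class GCTConfig:
    conv_layers: int = 2
    heads: int = 4
    dim: int = 512
    ffn_hidden: int | None = None  # default 2 * dim
    dropout: float = 0.5
    distance_cap: int = 10
    use_attention: bool = True
    use_graph_conv: bool = True
    use_gaussian_bias: bool = True

    def __post_init__(self):
        if self.conv_layers < 1 or self.heads < 1:
            raise ValueError("conv_layers and heads must be >= 1")
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads")
        if self.ffn_hidden is None:
            self.ffn_hidden = 2 * self.dim

    @property
    def head_dim(self) -> int:
        return self.dim // self.heads


@dataclass
class GCTState:
    conv_weights: list[Tensor]
    w_query: list[Tensor]
    w_key: list[Tensor]
    w_value: list[Tensor]
    w_out: Tensor
    omega: Tensor
    bias_b: Tensor
    ln1_gain: Tensor
    ln1_offset: Tensor
    ln2_gain: Tensor
    ln2_offset: Tensor
    ffn_w1: Tensor
    ffn_b1: Tensor
    ffn_w2: Tensor
    ffn_b2: Tensor

    def named_params(self, prefix: str = "gct"):
        for e, w in enumerate(self.conv_weights):
            yield f"{prefix}.conv.{e}.W", w
        for q in range(len(self.w_query)):
            yield f"{prefix}.head.{q}.W_Q", self.w_query[q]
            yield f"{prefix}.head.{q}.W_K", self.w_key[q]
            yield f"{prefix}.head.{q}.W_V", self.w_value[q]
        yield f"{prefix}.W_O", self.w_out
        yield f"{prefix}.omega", self.omega
        yield f"{prefix}.b", self.bias_b
        yield f"{prefix}.ln1.gain", self.ln1_gain
        yield f"{prefix}.ln1.offset", self.ln1_offset
        yield f"{prefix}.ln2.gain", self.ln2_gain
        yield f"{prefix}.ln2.offset", self.ln2_offset
        yield f"{prefix}.ffn.W1", self.ffn_w1
        yield f"{prefix}.ffn.b1", self.ffn_b1
        yield f"{prefix}.ffn.W2", self.ffn_w2
        yield f"{prefix}.ffn.b2", self.ffn_b2


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_gct_state(config: GCTConfig, in_dim: int, rng: np.random.Generator) -> GCTState:
    """Xavier matrices, zero biases, unit layer-norm gains, omega=1, b=0.

    Without the graph-conv stack a single linear projection (stored as
    the lone conv weight) maps the raw features to width D.
    """
    d, dh = config.dim, config.head_dim
    conv = []
    cur = in_dim
    n_layers = config.conv_layers if config.use_graph_conv else 1
    for _ in range(n_layers):
        conv.append(parameter(_xavier(rng, cur, d)))
        cur = d
    return GCTState(
        conv_weights=conv,
        w_query=[parameter(_xavier(rng, d, dh)) for _ in range(config.heads)],
        w_key=[parameter(_xavier(rng, d, dh)) for _ in range(config.heads)],
        w_value=[parameter(_xavier(rng, d, dh)) for _ in range(config.heads)],
        w_out=parameter(_xavier(rng, config.heads * dh, d)),
        omega=parameter(np.array(1.0)),
        bias_b=parameter(np.array(0.0)),
        ln1_gain=parameter(np.ones(d)),
        ln1_offset=parameter(np.zeros(d)),
        ln2_gain=parameter(np.ones(d)),
        ln2_offset=parameter(np.zeros(d)),
        ffn_w1=parameter(_xavier(rng, d, config.ffn_hidden)),
        ffn_b1=parameter(np.zeros(config.ffn_hidden)),
        ffn_w2=parameter(_xavier(rng, config.ffn_hidden, d)),
        ffn_b2=parameter(np.zeros(d)),
    )


# ---------------------------------------------------------------------------
# Per-operation math (plain numpy)


def graph_conv_stack(
    features: np.ndarray, norm_adjacency: np.ndarray, weights: list[np.ndarray]
) -> np.ndarray:
    """X^(e) = ReLU(A_hat X^(e-1) W^(e)) applied over the weight list."""
    x = np.asarray(features, dtype=np.float64)
    for w in weights:
        x = np.maximum(norm_adjacency @ x @ w, 0.0)
    return x


def gaussian_bias(hop: np.ndarray, omega: float, b: float) -> np.ndarray:
    """Non-positive attention bias ``-|omega * k^2 + b|`` from hop distances."""
    hop = np.asarray(hop, dtype=np.float64)
    if (hop < 0).any():
        raise ValueError("hop distances must be nonnegative")
    return -np.abs(omega * hop**2 + b)


def biased_attention_head(
    x: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    bias: np.ndarray,
    d: int,
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d) + bias) V for one head."""
    if d <= 0:
        raise ValueError("head dimension must be positive")
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    logits = q @ k.T / np.sqrt(d) + bias
    logits -= logits.max(axis=1, keepdims=True)
    s = np.exp(logits)
    s /= s.sum(axis=1, keepdims=True)
    return s @ v


def concat_heads(head_outputs: list[np.ndarray], w_out: np.ndarray) -> np.ndarray:
    """Horizontal concatenation of head outputs followed by the output map."""
    rows = {h.shape[0] for h in head_outputs}
    if len(rows) != 1:
        raise ValueError("head outputs must share their row count")
    return np.concatenate(head_outputs, axis=1) @ w_out


def _layer_norm_np(x: np.ndarray, gain: np.ndarray, offset: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    return (x - mu) / np.sqrt(var + _LN_EPS) * gain + offset


def transformer_block(x_l: np.ndarray, attn_out: np.ndarray, ffn: dict) -> np.ndarray:
    """Residual + layer-norm + feed-forward: H = LN(FFN(A~) + A~), A~ = LN(attn + X)."""
    a_tilde = _layer_norm_np(attn_out + x_l, ffn["ln1_gain"], ffn["ln1_offset"])
    hidden = np.maximum(a_tilde @ ffn["w1"] + ffn["b1"], 0.0)
    return _layer_norm_np(
        hidden @ ffn["w2"] + ffn["b2"] + a_tilde, ffn["ln2_gain"], ffn["ln2_offset"]
    )


# ---------------------------------------------------------------------------
# Tape-based encoder


def encode_gct(
    graph: HeterogeneousGraph,
    config: GCTConfig,
    state: GCTState,
    rng: np.random.Generator | None = None,
    training: bool = False,
    features: Tensor | None = None,
) -> Tensor:
    """Full GCT forward pass producing the (M+N) x D embedding H_TR."""
    x = features if features is not None else constant(graph.features)
    if config.use_graph_conv:
        a_hat = constant(graph.norm_adjacency)
        for w in state.conv_weights:
            x = (a_hat @ (x @ w)).relu()
    else:
        x = x @ state.conv_weights[0]
    if not config.use_attention:
        return x

    n = graph.n_nodes
    if config.use_gaussian_bias:
        k2 = constant(np.minimum(graph.hop_distance, config.distance_cap) ** 2)
        bias = -((state.omega * k2 + state.bias_b).abs())
    else:
        bias = constant(np.zeros((n, n)))
    x = x.dropout(config.dropout, rng, training)
    heads = []
    scale = 1.0 / np.sqrt(config.head_dim)
    for q in range(config.heads):
        qm = x @ state.w_query[q]
        km = x @ state.w_key[q]
        vm = x @ state.w_value[q]
        logits = (qm @ km.T) * scale + bias
        attn = logits.softmax_rows()
        assert np.allclose(attn.value.sum(axis=1), 1.0, atol=1e-6)
        heads.append(attn @ vm)
    cat = heads[0]
    for h in heads[1:]:
        cat = cat.concat(h, axis=1)
    attn_out = cat @ state.w_out
    a_tilde = (attn_out + x).layer_norm_rows(_LN_EPS) * state.ln1_gain + state.ln1_offset
    hidden = (a_tilde @ state.ffn_w1 + state.ffn_b1).relu()
    ffn_out = hidden @ state.ffn_w2 + state.ffn_b2
    h_tr = (ffn_out + a_tilde).layer_norm_rows(_LN_EPS) * state.ln2_gain + state.ln2_offset
    return h_tr
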