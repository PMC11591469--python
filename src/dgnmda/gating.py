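"""Fine-grained multi-layer feature-interaction gating.

The two encoder embeddings H_AG (attention encoder) and H_TR
(transformer encoder) are fused elementwise: a sigmoid gate
``G = sigmoid(W_g [H_a || H_b] + b_g)`` sets a per-node, per-dimension
mixing ratio, the gated convex combination is augmented by a residual
mean of the two inputs and by a tanh interaction unit
``F = tanh(W_f [H_a || H_b] + b_f)``, and dropout regularises the
output.  The layer is applied recursively: layer 1 consumes
(H_AG, H_TR) and each later layer consumes (previous output, H_TR);
a "parallel" alternative runs a mirrored second stream with swapped
operands.

The concatenation-plus-linear replacement used in ablations lives here
as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, parameter

__all__ = [
    "GatingConfig",
    "GatingState",
    "init_gating_state",
    "gate_weights",
    "gated_fusion",
    "gating_layer",
    "fuse_multilayer",
    "concat_linear_fusion",
]


@dataclass
class GatingConfig:
    depth: int = 2
    dim: int = 512
    dropout: float = 0.5
    recursion: str = "with_transformer"  # or "parallel"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("gating depth must be >= 1")
        if self.recursion not in ("with_transformer", "parallel"):
            raise ValueError(f"unknown recursion mode {self.recursion!r}")


@dataclass
class GatingState:
    gate_w: list[Tensor]  # per layer, (2D, D)
    gate_b: list[Tensor]
    inter_w: list[Tensor]
    inter_b: list[Tensor]

    def named_params(self, prefix: str = "gating"):
        for i in range(len(self.gate_w)):
            yield f"{prefix}.{i}.W_g", self.gate_w[i]
            yield f"{prefix}.{i}.b_g", self.gate_b[i]
            yield f"{prefix}.{i}.W_f", self.inter_w[i]
            yield f"{prefix}.{i}.b_f", self.inter_b[i]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_gating_state(config: GatingConfig, rng: np.random.Generator) -> GatingState:
    d = config.dim
    return GatingState(
        gate_w=[parameter(_xavier(rng, 2 * d, d)) for _ in range(config.depth)],
        gate_b=[parameter(np.zeros(d)) for _ in range(config.depth)],
        inter_w=[parameter(_xavier(rng, 2 * d, d)) for _ in range(config.depth)],
        inter_b=[parameter(np.zeros(d)) for _ in range(config.depth)],
    )


# ---------------------------------------------------------------------------
# Per-operation math (numpy in, numpy out; Tensors pass through the same code)


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def gate_weights(h_a, h_b, w_g, b_g):
    """G = sigmoid([H_a || H_b] W_g + b_g), entries strictly in (0, 1)."""
    as_tensor = isinstance(h_a, Tensor)
    h_a, h_b = _lift(h_a), _lift(h_b)
    if h_a.shape != h_b.shape:
        raise ValueError("gate inputs must share shape")
    g = (h_a.concat(h_b, axis=1) @ _lift(w_g) + _lift(b_g)).sigmoid()
    return g if as_tensor else g.value


def gated_fusion(g, h_a, h_b):
    """Elementwise convex combination G * H_a + (1 - G) * H_b."""
    as_tensor = isinstance(h_a, Tensor)
    g, h_a, h_b = _lift(g), _lift(h_a), _lift(h_b)
    out = g * h_a + (1.0 - g) * h_b
    return out if as_tensor else out.value


def gating_layer(
    h_a,
    h_b,
    w_g,
    b_g,
    w_f,
    b_f,
    p: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
):
    """One gating layer: gate, fuse, residual mean, interaction, dropout."""
    as_tensor = isinstance(h_a, Tensor)
    ha, hb = _lift(h_a), _lift(h_b)
    wg, bg, wf, bf = _lift(w_g), _lift(b_g), _lift(w_f), _lift(b_f)
    g = (ha.concat(hb, axis=1) @ wg + bg).sigmoid()
    h_fused = g * ha + (1.0 - g) * hb
    h_res = h_fused + (ha + hb) / 2.0
    f = (ha.concat(hb, axis=1) @ wf + bf).tanh()
    h_out = (h_res + f).dropout(p, rng, training)
    return h_out if as_tensor else h_out.value


def fuse_multilayer(
    h_ag,
    h_tr,
    config: GatingConfig,
    state: GatingState,
    rng: np.random.Generator | None = None,
    training: bool = False,
):
    """Recursive application of ``config.depth`` gating layers."""
    if len(state.gate_w) != config.depth:
        raise ValueError("state depth does not match config depth")
    as_tensor = isinstance(h_ag, Tensor)
    a, b = _lift(h_ag), _lift(h_tr)
    if config.recursion == "parallel":
        a2, b2 = a, b
        for i in range(config.depth):
            layer = (state.gate_w[i], state.gate_b[i], state.inter_w[i], state.inter_b[i])
            a_next = gating_layer(a2, b2, *layer, p=config.dropout, rng=rng, training=training)
            b_next = gating_layer(b2, a2, *layer, p=config.dropout, rng=rng, training=training)
            a2, b2 = _lift(a_next), _lift(b_next)
        out = a2
    else:
        cur = a
        for i in range(config.depth):
            cur = _lift(
                gating_layer(
                    cur,
                    b,
                    state.gate_w[i],
                    state.gate_b[i],
                    state.inter_w[i],
                    state.inter_b[i],
                    p=config.dropout,
                    rng=rng,
                    training=training,
                )
            )
        out = cur
    return out if as_tensor else out.value


def concat_linear_fusion(h_ag, h_tr, w_c):
    """Ablation fusion: plain concatenation followed by a linear map to D."""
    out = _lift(h_ag).concat(_lift(h_tr), axis=1) @ _lift(w_c)
    return out if isinstance(h_ag, Tensor) else out.value
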