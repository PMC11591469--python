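"""Independent brute-force reference implementations used only by tests.

These walk the encoder equations node by node and head by head with
explicit Python loops, sharing no code with the vectorised tape-based
encoders they check.
"""

import numpy as np


def _leaky(x, slope):
    return x if x > 0 else slope * x


def _softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


def gcan_oracle(graph, config, state):
    """Dense loop evaluation of the attention encoder forward pass."""
    x = graph.features.astype(float).copy()
    n = x.shape[0]
    nbrs = [list(map(int, graph.neighbor_lists[i])) for i in range(n)]
    deg = np.array([len(nb) + 1 for nb in nbrs], dtype=float)
    if config.use_gcn_pre:
        for w_t in state.gcn_weights:
            w = w_t.value
            out = np.zeros((n, w.shape[1]))
            for i in range(n):
                acc = np.zeros(w.shape[1])
                for j in dict.fromkeys(nbrs[i] + [i]):  # the union N(i) | {i}
                    acc += (w.T @ x[j]) / np.sqrt(deg[i] * deg[j])
                out[i] = np.maximum(acc, 0.0)
            x = out
    layer_outs = []
    for layer in range(config.att_layers):
        heads = []
        for q in range(config.heads):
            w_h = state.head_transforms[layer][q].value
            a = state.attention_vectors[layer][q].value
            dh = w_h.shape[1]
            z = np.zeros((n, dh))
            for i in range(n):
                coeffs = []
                for j in nbrs[i]:
                    pair = np.concatenate([x[i] @ w_h, x[j] @ w_h])
                    coeffs.append(_leaky(float(a @ pair), config.leaky_relu_slope))
                alpha = _softmax(np.array(coeffs))
                acc = np.zeros(dh)
                for weight, j in zip(alpha, nbrs[i]):
                    acc += weight * (x[j] @ w_h)
                z[i] = np.maximum(acc, 0.0)
            heads.append(z)
        out = np.concatenate(heads, axis=1)
        layer_outs.append(out)
        x = out
    h = layer_outs[-1].copy()
    for layer in range(config.att_layers - 1):
        h = h + state.skip_weights.value[layer] * layer_outs[layer]
    return h


def _layer_norm(row, gain, offset, eps=1e-5):
    mu = row.mean()
    var = ((row - mu) ** 2).mean()
    return (row - mu) / np.sqrt(var + eps) * gain + offset


def gct_oracle(graph, config, state):
    """Dense loop evaluation of the transformer encoder forward pass."""
    x = graph.features.astype(float).copy()
    n = x.shape[0]
    if config.use_graph_conv:
        for w_t in state.conv_weights:
            x = np.maximum(graph.norm_adjacency @ x @ w_t.value, 0.0)
    else:
        x = x @ state.conv_weights[0].value
    if not config.use_attention:
        return x
    omega, b = float(state.omega.value), float(state.bias_b.value)
    k = np.minimum(graph.hop_distance, config.distance_cap).astype(float)
    if config.use_gaussian_bias:
        bias = -np.abs(omega * k**2 + b)
    else:
        bias = np.zeros((n, n))
    heads = []
    for q in range(config.heads):
        qm = x @ state.w_query[q].value
        km = x @ state.w_key[q].value
        vm = x @ state.w_value[q].value
        out = np.zeros_like(vm)
        for i in range(n):
            logits = np.array(
                [qm[i] @ km[j] / np.sqrt(config.head_dim) + bias[i, j] for j in range(n)]
            )
            alpha = _softmax(logits)
            for j in range(n):
                out[i] += alpha[j] * vm[j]
        heads.append(out)
    attn = np.concatenate(heads, axis=1) @ state.w_out.value
    a_tilde = np.zeros_like(x)
    for i in range(n):
        a_tilde[i] = _layer_norm(attn[i] + x[i], state.ln1_gain.value, state.ln1_offset.value)
    h = np.zeros_like(x)
    for i in range(n):
        hidden = np.maximum(a_tilde[i] @ state.ffn_w1.value + state.ffn_b1.value, 0.0)
        ffn = hidden @ state.ffn_w2.value + state.ffn_b2.value
        h[i] = _layer_norm(ffn + a_tilde[i], state.ln2_gain.value, state.ln2_offset.value)
    return h


def gating_oracle(h_ag, h_tr, config, state):
    """Hand-unrolled recursion of the gating fusion (with_transformer mode)."""

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    cur = h_ag.astype(float)
    for i in range(config.depth):
        cat = np.concatenate([cur, h_tr], axis=1)
        g = sigmoid(cat @ state.gate_w[i].value + state.gate_b[i].value)
        fused = g * cur + (1 - g) * h_tr
        res = fused + (cur + h_tr) / 2.0
        f = np.tanh(cat @ state.inter_w[i].value + state.inter_b[i].value)
        cur = res + f
    return cur
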